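"""The allosteric/orthosteric site database and per-residue annotations.

Sites are consumed as residue sets in 1-based UniProt sequence coordinates
(PDB author numbering is never used; the pdb_id field is annotation only).
Predicted-allosteric records represent upstream pocket predictions taken as
given data — no site prediction happens here.

The "Mapping Area" choice is modelled as a mode: in ALLOSTERIC mode the
orthosteric records are loaded but inactive for mapping; in FUNCTIONAL mode
all three site types are active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from .formats_io import AA_ALPHABET, FormatError

SITE_TYPES = ("ALLO_EXP", "ALLO_PRED", "ORTHO")
MODES = ("ALLOSTERIC", "FUNCTIONAL")

# canonical listing order for sites_for()
_TYPE_ORDER = {"ORTHO": 0, "ALLO_EXP": 1, "ALLO_PRED": 2}


@dataclass(frozen=True)
class SiteRecord:
    uniprot_id: str
    gene_symbol: str
    pdb_id: str
    site_id: str
    site_type: str
    residues: frozenset[int]

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise FormatError(f"invalid site_type {self.site_type!r}")
        if not self.residues:
            raise FormatError(f"site {self.site_id} has no residues")


@dataclass(frozen=True)
class ResidueAnnotation:
    uniprot_id: str
    position: int
    wt_aa: str
    rsa: float   # relative solvent accessibility, [0, 1]
    flex: float  # z-scored flexibility proxy (e.g. normalized B-factor)


@dataclass
class SiteDatabase:
    sites_by_protein: dict[str, list[SiteRecord]]
    residue_annotations: dict[tuple[str, int], ResidueAnnotation]
    gene_map: dict[str, str]
    mode: str = "FUNCTIONAL"
    _counts: dict[str, int] = field(default_factory=dict)

    @property
    def active_types(self) -> tuple[str, ...]:
        return ("ALLO_EXP", "ALLO_PRED") if self.mode == "ALLOSTERIC" else SITE_TYPES

    def counts(self) -> dict[str, int]:
        """Number of loaded site records per site type (mode-independent)."""
        return dict(self._counts)

    def annotation(self, uniprot_id: str, position: int) -> ResidueAnnotation | None:
        return self.residue_annotations.get((uniprot_id, position))

    def proteins(self) -> list[str]:
        return sorted(self.sites_by_protein)

    def active_residues(self, uniprot_id: str) -> set[int]:
        """Union of residue positions of the protein's active sites."""
        out: set[int] = set()
        for rec in sites_for(self, uniprot_id):
            out |= rec.residues
        return out


def _parse_residues(text: str) -> frozenset[int]:
    try:
        vals = frozenset(int(tok) for tok in str(text).split(",") if tok.strip())
    except ValueError as e:
        raise FormatError(f"non-integer residue in {text!r}") from e
    if any(v < 1 for v in vals):
        raise FormatError(f"residue positions must be >= 1 in {text!r}")
    return vals


def load_site_db(
    sites_path: str | Path,
    residues_path: str | Path,
    genemap_path: str | Path,
    mode: str = "FUNCTIONAL",
) -> SiteDatabase:
    """Load and index the site, residue-annotation, and gene-map TSVs."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    sites_df = pd.read_csv(sites_path, sep="\t", dtype=str, keep_default_na=False)
    need = {"uniprot_id", "gene_symbol", "pdb_id", "site_id", "site_type", "residues"}
    if missing := need - set(sites_df.columns):
        raise FormatError(f"sites table missing columns {sorted(missing)}")
    seen: set[tuple[str, str]] = set()
    sites_by_protein: dict[str, list[SiteRecord]] = {}
    counts = {t: 0 for t in SITE_TYPES}
    for _, row in sites_df.iterrows():
        key = (row["uniprot_id"], row["site_id"])
        if key in seen:
            raise FormatError(f"duplicate site {key}")
        seen.add(key)
        rec = SiteRecord(
            uniprot_id=row["uniprot_id"],
            gene_symbol=row["gene_symbol"],
            pdb_id=row["pdb_id"],
            site_id=row["site_id"],
            site_type=row["site_type"],
            residues=_parse_residues(row["residues"]),
        )
        sites_by_protein.setdefault(rec.uniprot_id, []).append(rec)
        counts[rec.site_type] += 1

    res_df = pd.read_csv(residues_path, sep="\t", dtype={"position": int, "rsa": float, "flex": float})
    need = {"uniprot_id", "position", "wt_aa", "rsa", "flex"}
    if missing := need - set(res_df.columns):
        raise FormatError(f"residue table missing columns {sorted(missing)}")
    annotations: dict[tuple[str, int], ResidueAnnotation] = {}
    for _, row in res_df.iterrows():
        if not 0.0 <= row["rsa"] <= 1.0:
            raise FormatError(
                f"rsa outside [0,1] at {row['uniprot_id']}:{row['position']}"
            )
        if row["wt_aa"] not in AA_ALPHABET:
            raise FormatError(f"invalid wt_aa {row['wt_aa']!r}")
        key = (row["uniprot_id"], int(row["position"]))
        if key in annotations:
            raise FormatError(f"duplicate residue annotation {key}")
        annotations[key] = ResidueAnnotation(
            key[0], key[1], row["wt_aa"], float(row["rsa"]), float(row["flex"])
        )

    gm_df = pd.read_csv(genemap_path, sep="\t", dtype=str)
    if missing := {"gene_symbol", "uniprot_id"} - set(gm_df.columns):
        raise FormatError(f"gene map missing columns {sorted(missing)}")
    gene_map = dict(zip(gm_df["gene_symbol"], gm_df["uniprot_id"]))
    mapped = set(gene_map.values())
    orphans = set(sites_by_protein) - mapped
    if orphans:
        raise FormatError(f"site proteins absent from gene map: {sorted(orphans)}")

    return SiteDatabase(sites_by_protein, annotations, gene_map, mode, counts)


def sites_for(db: SiteDatabase, uniprot_id: str) -> list[SiteRecord]:
    """Active site records for a protein, in canonical deterministic order.

    Order: ORTHO, then ALLO_EXP, then ALLO_PRED; site_id lexicographic within
    a type.  Unknown proteins yield an empty list.
    """
    recs = [
        r
        for r in db.sites_by_protein.get(uniprot_id, [])
        if r.site_type in db.active_types
    ]
    return sorted(recs, key=lambda r: (_TYPE_ORDER[r.site_type], r.site_id))


def validate_against_fasta(db: SiteDatabase, seqs: dict[str, str]) -> list[str]:
    """Cross-check residue annotations and site positions against sequences.

    Returns a list of violation messages (wt_aa disagreement, position past
    the sequence end).  Violations are reported, never silently dropped.
    """
    violations: list[str] = []
    for (uid, pos), ann in db.residue_annotations.items():
        seq = seqs.get(uid)
        if seq is None:
            continue
        if pos > len(seq):
            violations.append(f"{uid}:{pos} beyond sequence length {len(seq)}")
        elif seq[pos - 1] != ann.wt_aa:
            violations.append(
                f"{uid}:{pos} annotation wt {ann.wt_aa} != sequence {seq[pos - 1]}"
            )
    for uid, recs in db.sites_by_protein.items():
        seq = seqs.get(uid)
        if seq is None:
            continue
        for rec in recs:
            for pos in rec.residues:
                if pos > len(seq):
                    violations.append(
                        f"site {uid}/{rec.site_id} residue {pos} beyond sequence end"
                    )
    return violations
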