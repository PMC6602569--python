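"""Assign mutations to the four areas and build per-sample area profiles.

Every mutation lands in exactly one of ALLO_EXP, ALLO_PRED, ORTHO or OTHER
(a partition — the four counts always sum to the number of mutations).
When a position belongs to several overlapping sites the default precedence
is ORTHO > ALLO_EXP > ALLO_PRED: orthosteric membership is the more specific
functional claim and keeps the four-area accounting mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .formats_io import Cohort, Mutation, ValidationConfig
from .site_db import SiteDatabase, sites_for

logger = logging.getLogger(__name__)

AREAS = ("ALLO_EXP", "ALLO_PRED", "ORTHO", "OTHER")
DEFAULT_PRECEDENCE = ("ORTHO", "ALLO_EXP", "ALLO_PRED")


@dataclass(frozen=True)
class MappedMutation:
    mutation: Mutation
    area: str
    site_id: str | None
    pdb_id: str | None
    ref_check: str  # match | mismatch | unknown
    uniprot_id: str = ""

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(f"invalid area {self.area!r}")
        if self.area != "OTHER" and self.site_id is None:
            raise ValueError("site-mapped mutation must carry a site_id")
        if self.area == "OTHER" and self.site_id is not None:
            raise ValueError("OTHER-area mutation cannot carry a site_id")

    @property
    def scoreable(self) -> bool:
        return self.area != "OTHER" and self.ref_check != "mismatch"


@dataclass
class AreaProfile:
    sample_id: str
    counts: dict[str, int]
    per_protein: dict[str, dict[str, int]]


@dataclass
class MappingReport:
    skipped_unknown_gene: list[str] = field(default_factory=list)
    skipped_ref_mismatch: list[str] = field(default_factory=list)

    def rows(self) -> list[dict]:
        out = [
            {"mutation": m, "action": "skip_unknown_gene"}
            for m in self.skipped_unknown_gene
        ]
        out += [
            {"mutation": m, "action": "skip_ref_mismatch"}
            for m in self.skipped_ref_mismatch
        ]
        return out


def map_mutation(
    m: Mutation,
    db: SiteDatabase,
    seqs: dict[str, str] | None = None,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> MappedMutation:
    """Map one mutation to its area by residue-set membership.

    The gene symbol is resolved to a UniProt accession through the database's
    gene map unless the mutation already carries one.  ``ref_check`` compares
    the stated reference residue with the FASTA sequence when available; a
    position beyond the sequence end is a mismatch and forces area OTHER.
    Pure function: identical inputs give identical outputs.
    """
    uid = m.uniprot_id or db.gene_map.get(m.gene_symbol, "")
    if not uid:
        return MappedMutation(m, "OTHER", None, None, "unknown", "")

    ref_check = "unknown"
    if seqs and uid in seqs:
        seq = seqs[uid]
        if m.position > len(seq):
            logger.warning(
                "%s %s position %d beyond sequence length %d",
                m.gene_symbol, m.change, m.position, len(seq),
            )
            return MappedMutation(m, "OTHER", None, None, "mismatch", uid)
        ref_check = "match" if seq[m.position - 1] == m.ref_aa else "mismatch"

    hits_by_type: dict[str, list] = {}
    for rec in sites_for(db, uid):
        if m.position in rec.residues:
            hits_by_type.setdefault(rec.site_type, []).append(rec)
    for area in precedence:
        if area in hits_by_type and area in db.active_types:
            rec = min(hits_by_type[area], key=lambda r: r.site_id)
            return MappedMutation(m, area, rec.site_id, rec.pdb_id, ref_check, uid)
    return MappedMutation(m, "OTHER", None, None, ref_check, uid)


def map_cohort(
    cohort: Cohort,
    db: SiteDatabase,
    seqs: dict[str, str] | None = None,
    cfg: ValidationConfig | None = None,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> tuple[list[MappedMutation], MappingReport]:
    """Map every mutation of a validated cohort, applying the mismatch policy.

    Under ``on_ref_mismatch=skip_warn`` (default) a mutation whose stated
    reference residue disagrees with the sequence is demoted to OTHER — kept
    in the frequency profiles but excluded from scoring; ``error`` raises.
    Unknown genes follow ``on_unknown_gene`` the same way.
    """
    cfg = cfg or ValidationConfig()
    report = MappingReport()
    mapped: list[MappedMutation] = []
    for sample_muts in cohort.samples.values():
        for m in sample_muts:
            mm = map_mutation(m, db, seqs, precedence)
            tag = f"{m.sample_id}:{m.gene_symbol}:{m.change}"
            if mm.ref_check == "unknown" and not mm.uniprot_id:
                if cfg.on_unknown_gene == "error":
                    raise ValueError(f"unknown gene {m.gene_symbol}")
                report.skipped_unknown_gene.append(tag)
            elif mm.ref_check == "mismatch":
                if cfg.on_ref_mismatch == "error":
                    raise ValueError(f"reference residue mismatch for {tag}")
                report.skipped_ref_mismatch.append(tag)
                if mm.area != "OTHER":
                    mm = MappedMutation(m, "OTHER", None, None, "mismatch", mm.uniprot_id)
            mapped.append(mm)
    return mapped, report


def area_profile(mapped: list[MappedMutation], sample_id: str) -> AreaProfile:
    """Tally one sample's mutations over the four areas and per protein."""
    counts = {a: 0 for a in AREAS}
    per_protein: dict[str, dict[str, int]] = {}
    for mm in mapped:
        if mm.mutation.sample_id != sample_id:
            continue
        counts[mm.area] += 1
        row = per_protein.setdefault(mm.mutation.gene_symbol, {a: 0 for a in AREAS})
        row[mm.area] += 1
    return AreaProfile(sample_id, counts, per_protein)


def write_area_profile(profiles: list[AreaProfile], path: str | Path) -> None:
    rows = [
        {"sample": p.sample_id, "area": a, "count": p.counts[a]}
        for p in profiles
        for a in AREAS
    ]
    pd.DataFrame(rows, columns=["sample", "area", "count"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_per_protein_profile(profiles: list[AreaProfile], path: str | Path) -> None:
    rows = [
        {"sample": p.sample_id, "gene_symbol": g, "area": a, "count": c[a]}
        for p in profiles
        for g, c in sorted(p.per_protein.items())
        for a in AREAS
        if c[a] > 0
    ]
    pd.DataFrame(rows, columns=["sample", "gene_symbol", "area", "count"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_mapping_report(
    mapped: list[MappedMutation], report: MappingReport, path: str | Path
) -> None:
    rows = []
    skip_mismatch = set(report.skipped_ref_mismatch)
    skip_gene = set(report.skipped_unknown_gene)
    for mm in mapped:
        m = mm.mutation
        tag = f"{m.sample_id}:{m.gene_symbol}:{m.change}"
        if tag in skip_mismatch:
            action = "skip_ref_mismatch"
        elif tag in skip_gene:
            action = "skip_unknown_gene"
        else:
            action = "mapped" if mm.area != "OTHER" else "off_site"
        rows.append(
            {
                "sample": m.sample_id,
                "gene_symbol": m.gene_symbol,
                "mutation": m.change,
                "area": mm.area,
                "site_id": mm.site_id or "",
                "ref_check": mm.ref_check,
                "action": action,
            }
        )
    pd.DataFrame(
        rows,
        columns=["sample", "gene_symbol", "mutation", "area", "site_id", "ref_check", "action"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
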