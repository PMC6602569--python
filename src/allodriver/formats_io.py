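"""Readers and writers for every external table the pipeline touches.

Input side: MAF cohorts, single-sample ANNOVAR gene-annotation output, the
``sample;gene;V600E`` one-mutation-per-line grammar, UniProt-keyed FASTA,
and labeled driver/passenger mutation tables.  Output side: the ranked
"Target Result" table.  Everything operates purely in protein (HGVS)
coordinates; genomic columns are deliberately ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Columns of the Target Result table, in order.
TARGET_COLUMNS = (
    "Sample",
    "Gene/Protein",
    "UniProt ID",
    "Driver mutation",
    "Location",
    "Area",
    "Score",
)


class FormatError(ValueError):
    """A file violated its declared grammar or schema."""


@dataclass(frozen=True)
class Mutation:
    """One missense substitution in one sample, in 1-based protein coordinates."""

    sample_id: str
    gene_symbol: str
    ref_aa: str
    position: int
    alt_aa: str
    uniprot_id: str = ""

    def __post_init__(self) -> None:
        if self.ref_aa not in AA_ALPHABET or self.alt_aa not in AA_ALPHABET:
            raise FormatError(
                f"non-standard residue in {self.ref_aa}{self.position}{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise FormatError(
                f"synonymous change {self.ref_aa}{self.position}{self.alt_aa}"
            )
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")

    @property
    def change(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class Cohort:
    """Mutations grouped by sample; insertion order is preserved everywhere."""

    samples: dict[str, list[Mutation]]
    source_format: str  # MAF | ANNOVAR | LIST

    def n_mutations(self) -> int:
        return sum(len(v) for v in self.samples.values())


@dataclass
class ValidationConfig:
    max_mutations_per_sample: int = 2000
    on_unknown_gene: str = "skip_warn"  # or "error"
    on_ref_mismatch: str = "skip_warn"  # or "error"

    def __post_init__(self) -> None:
        if self.max_mutations_per_sample < 1:
            raise ValueError("max_mutations_per_sample must be >= 1")
        for f in (self.on_unknown_gene, self.on_ref_mismatch):
            if f not in ("skip_warn", "error"):
                raise ValueError(f"invalid policy {f!r}")


@dataclass
class ValidationReport:
    rejected_samples: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


_THREE_LETTER = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_ONE_LETTER = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Decompose ``V600E`` / ``p.V600E`` / ``p.Val600Glu`` into (ref, pos, alt).

    Three-letter codes are normalized to one-letter.  Raises ``FormatError``
    for anything else (frameshifts, indels, missing residues).
    """
    s = text.strip()
    if s.startswith("p."):
        s = s[2:]
    m = _ONE_LETTER.match(s)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _THREE_LETTER.match(s)
        if not m:
            raise FormatError(f"cannot parse protein change {text!r}")
        try:
            ref = protein_letters_3to1[m.group(1)]
            alt = protein_letters_3to1[m.group(3)]
        except KeyError as e:
            raise FormatError(f"unknown residue code in {text!r}") from e
        pos = int(m.group(2))
    if ref not in AA_ALPHABET or alt not in AA_ALPHABET:
        raise FormatError(f"non-standard residue in {text!r}")
    return ref, pos, alt


def parse_mutation_list(text: str) -> tuple[list[Mutation], list[str]]:
    """Parse the ``sample;gene;V600E`` line grammar.

    Returns (mutations, rejected) where *rejected* holds human-readable
    reasons for lines that parsed but were invalid as mutations (e.g. a
    synonymous change).  A malformed line raises ``FormatError`` naming
    the 1-based line number.
    """
    mutations: list[Mutation] = []
    rejected: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(";")]
        if len(parts) != 3 or not all(parts):
            raise FormatError(f"line {lineno}: expected 'sample;gene;RefPosAlt', got {raw!r}")
        sample, gene, change = parts
        try:
            ref, pos, alt = parse_protein_change(change)
        except FormatError as e:
            raise FormatError(f"line {lineno}: {e}") from e
        if ref == alt:
            rejected.append(f"line {lineno}: synonymous change {change} rejected")
            continue
        mutations.append(Mutation(sample, gene, ref, pos, alt))
    return mutations, rejected


def cohort_from_mutations(mutations: Iterable[Mutation], source_format: str) -> Cohort:
    samples: dict[str, list[Mutation]] = {}
    for m in mutations:
        samples.setdefault(m.sample_id, []).append(m)
    return Cohort(samples=samples, source_format=source_format)


_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "HGVSp_Short")


def parse_maf(path: str | Path) -> Cohort:
    """Read a MAF file, keeping only parseable Missense_Mutation rows."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"MAF missing column {col!r}")
    df = df[df["Variant_Classification"] == "Missense_Mutation"]
    mutations: list[Mutation] = []
    for idx, row in df.iterrows():
        try:
            ref, pos, alt = parse_protein_change(row["HGVSp_Short"])
            mutations.append(
                Mutation(row["Tumor_Sample_Barcode"], row["Hugo_Symbol"], ref, pos, alt)
            )
        except FormatError as e:
            logger.warning("MAF row %s skipped: %s", idx, e)
    return cohort_from_mutations(mutations, "MAF")


def parse_annovar(path: str | Path) -> Cohort:
    """Read ANNOVAR gene-annotation output as a single-sample cohort.

    All mutations in the file belong to one sample named after the file stem.
    Only rows marked ``nonsynonymous SNV`` with a parseable
    ``gene:transcript:exon:c.X:p.V600E`` field are retained.
    """
    path = Path(path)
    sample_id = path.stem
    mutations: list[Mutation] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            fields = raw.rstrip("\r\n").split("\t")
            if "nonsynonymous SNV" not in fields:
                continue
            for fld in fields:
                if ":p." not in fld:
                    continue
                # first comma-separated transcript record carries the change
                segs = fld.split(",")[0].split(":")
                gene = segs[0]
                pchange = next((s for s in segs if s.startswith("p.")), None)
                if pchange is None:
                    continue
                try:
                    ref, pos, alt = parse_protein_change(pchange)
                except FormatError:
                    continue
                mutations.append(Mutation(sample_id, gene, ref, pos, alt))
                break
    if not mutations:
        raise FormatError(f"no missense mutations found in {path}")
    return Cohort(samples={sample_id: mutations}, source_format="ANNOVAR")


def validate_cohort(cohort: Cohort, cfg: ValidationConfig | None = None) -> tuple[Cohort, ValidationReport]:
    """Reject samples exceeding the per-sample mutation cap.

    Accepted samples pass through with their mutation lists untouched.
    Raises ``FormatError`` if nothing survives.
    """
    cfg = cfg or ValidationConfig()
    report = ValidationReport()
    kept: dict[str, list[Mutation]] = {}
    for sample_id, muts in cohort.samples.items():
        if len(muts) > cfg.max_mutations_per_sample:
            reason = f"{len(muts)} mutations exceeds cap of {cfg.max_mutations_per_sample}"
            report.rejected_samples.append((sample_id, reason))
            logger.warning("sample %s rejected: %s", sample_id, reason)
            continue
        if not muts:
            report.warnings.append(f"sample {sample_id} has no mutations")
        kept[sample_id] = muts
    if not kept:
        raise FormatError("empty cohort after validation")
    return Cohort(samples=kept, source_format=cohort.source_format), report


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load protein sequences keyed by UniProt accession.

    UniProt-style headers (``sp|Q06124|PTN11_HUMAN``) use the second
    pipe-delimited field; plain headers use the whole id.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split("|")[1] if "|" in rec.id else rec.id
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise FormatError(f"record {acc}: non-amino-acid characters {sorted(bad)}")
        if acc in seqs:
            raise FormatError(f"duplicate accession {acc}")
        seqs[acc] = seq
    return seqs


def load_label_table(path: str | Path) -> pd.DataFrame:
    """Load a driver/passenger label table.

    Columns: uniprot_id, gene_symbol, ref_aa, position, alt_aa, label, source.
    Duplicate mutation keys with conflicting labels are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    required = {"uniprot_id", "gene_symbol", "ref_aa", "position", "alt_aa", "label", "source"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"label table missing columns {sorted(missing)}")
    bad = df[~df["label"].isin(["driver", "passenger"])]
    if len(bad):
        raise FormatError(f"invalid labels: {sorted(bad['label'].unique())}")
    key = ["uniprot_id", "position", "ref_aa", "alt_aa"]
    conflicts = df.groupby(key)["label"].nunique()
    if (conflicts > 1).any():
        raise FormatError("conflicting labels for identical mutation keys")
    return df


def write_target_table(ranked: Mapping[str, list], path: str | Path) -> None:
    """Write the Target Result TSV, score-descending within each sample."""
    rows = []
    for sample_id, entries in ranked.items():
        for e in entries:
            rows.append(
                {
                    "Sample": sample_id,
                    "Gene/Protein": e.gene_symbol,
                    "UniProt ID": e.uniprot_id,
                    "Driver mutation": e.driver_mutation,
                    "Location": e.location,
                    "Area": e.area,
                    "Score": f"{e.score:.6f}",
                }
            )
    df = pd.DataFrame(rows, columns=list(TARGET_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_target_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != TARGET_COLUMNS:
        raise FormatError(f"unexpected target-table columns {list(df.columns)}")
    return df
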