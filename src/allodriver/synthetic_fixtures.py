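"""Seeded generators for every input the pipeline needs.

Nothing here touches the network: site databases, residue annotations,
FASTA, MAF cohorts, labeled feature datasets and benchmark label tables are
all produced deterministically from a seed, and every generated artifact
passes the corresponding loader/validator by construction.

The labeled-dataset generator plants a two-Gaussian class structure whose
mean separation (d-prime, in pooled-sd units) controls task difficulty, and
defaults mirror the driver:passenger imbalance of curated benchmark sets
(~0.12 positives per negative, e.g. 73/582).  All tables it emits are
synthetic stand-ins, never curated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .driver_model import LabeledDataset
from .features import CONTINUOUS_INDICES, FLAG_INDICES, FeatureSchema, default_schema

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_SITE_TYPES = ("ALLO_EXP", "ALLO_PRED", "ORTHO")
_SITE_SIZE = 5  # residues per generated site


@dataclass
class FixtureSpec:
    n_proteins: int = 6
    sites_per_protein: int = 3
    seq_length: int = 120
    n_samples: int = 3
    muts_per_sample: int = 10
    frac_on_sites: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_proteins", "sites_per_protein", "seq_length", "n_samples", "muts_per_sample"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if not 0.0 <= self.frac_on_sites <= 1.0:
            raise ValueError("frac_on_sites must be in [0, 1]")


@dataclass
class SeparationSpec:
    n_pos: int = 73
    n_neg: int = 582
    dprime: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 rows per class")
        if self.dprime < 0:
            raise ValueError("dprime must be >= 0")


@dataclass
class SiteWorld:
    """A generated, mutually consistent set of pipeline inputs."""

    directory: Path
    sites_path: Path
    residues_path: Path
    genemap_path: Path
    fasta_path: Path
    sequences: dict[str, str]
    genes: dict[str, str]  # gene_symbol -> uniprot_id
    site_positions: dict[str, set[int]]  # uniprot_id -> union of site residues


def gen_site_world(spec: FixtureSpec, out_dir: str | Path) -> SiteWorld:
    """Generate site TSV, residue TSV, gene map and FASTA into *out_dir*.

    Every site residue exists in the sequence and the residue table, wild
    types agree with the FASTA, and site types cycle so each of the three
    types occurs.  Byte-identical output for a fixed spec.
    """
    if spec.sites_per_protein * _SITE_SIZE > spec.seq_length:
        raise ValueError("site residues would exceed sequence length")
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fasta_lines: list[str] = []
    site_rows = ["uniprot_id\tgene_symbol\tpdb_id\tsite_id\tsite_type\tresidues"]
    res_rows = ["uniprot_id\tposition\twt_aa\trsa\tflex"]
    gm_rows = ["gene_symbol\tuniprot_id"]
    sequences: dict[str, str] = {}
    genes: dict[str, str] = {}
    site_positions: dict[str, set[int]] = {}

    type_cursor = 0
    for i in range(spec.n_proteins):
        uid = f"P{10000 + i}"
        gene = f"GENE{i + 1}"
        seq = "".join(rng.choice(list(_AA), size=spec.seq_length))
        sequences[uid] = seq
        genes[gene] = uid
        gm_rows.append(f"{gene}\t{uid}")
        fasta_lines.append(f">sp|{uid}|{gene}_SYN synthetic fixture protein")
        fasta_lines.extend(seq[j : j + 60] for j in range(0, len(seq), 60))

        pool = rng.permutation(np.arange(1, spec.seq_length + 1))
        site_positions[uid] = set()
        for j in range(spec.sites_per_protein):
            residues = sorted(int(p) for p in pool[j * _SITE_SIZE : (j + 1) * _SITE_SIZE])
            stype = _SITE_TYPES[type_cursor % 3]
            type_cursor += 1
            pdb = f"{1 + (i % 9)}SY{chr(65 + j % 26)}"
            site_rows.append(
                f"{uid}\t{gene}\t{pdb}\tS{j + 1}\t{stype}\t"
                + ",".join(str(r) for r in residues)
            )
            site_positions[uid].update(residues)

        rsa = rng.uniform(0.0, 1.0, size=spec.seq_length)
        flex = rng.normal(0.0, 1.0, size=spec.seq_length)
        for pos in range(1, spec.seq_length + 1):
            res_rows.append(
                f"{uid}\t{pos}\t{seq[pos - 1]}\t{rsa[pos - 1]:.4f}\t{flex[pos - 1]:.4f}"
            )

    paths = {
        "sites": out / "sites.tsv",
        "residues": out / "residues.tsv",
        "genemap": out / "gene_map.tsv",
        "fasta": out / "proteins.fasta",
    }
    paths["sites"].write_text("\n".join(site_rows) + "\n", encoding="utf-8")
    paths["residues"].write_text("\n".join(res_rows) + "\n", encoding="utf-8")
    paths["genemap"].write_text("\n".join(gm_rows) + "\n", encoding="utf-8")
    paths["fasta"].write_text("\n".join(fasta_lines) + "\n", encoding="utf-8")
    return SiteWorld(
        directory=out,
        sites_path=paths["sites"],
        residues_path=paths["residues"],
        genemap_path=paths["genemap"],
        fasta_path=paths["fasta"],
        sequences=sequences,
        genes=genes,
        site_positions=site_positions,
    )


def _random_missense(rng: np.random.Generator, seq: str, pos: int) -> tuple[str, str]:
    ref = seq[pos - 1]
    alt = str(rng.choice([a for a in _AA if a != ref]))
    return ref, alt


def gen_cohort_maf(spec: FixtureSpec, world: SiteWorld, out_path: str | Path) -> Path:
    """Write a MAF cohort whose mutations hit site residues at a set rate.

    ``frac_on_sites`` of each sample's mutations land on site residues with
    the correct wild-type residue taken from the FASTA; the rest are placed
    off-site.  If more on-site mutations are requested than site residues
    exist, positions are drawn with replacement (with a warning).
    """
    rng = np.random.default_rng([spec.seed, 1])
    uids = sorted(world.sequences)
    gene_of = {u: g for g, u in world.genes.items()}
    on_pool = [(u, p) for u in uids for p in sorted(world.site_positions[u])]
    off_pool = [
        (u, p)
        for u in uids
        for p in range(1, len(world.sequences[u]) + 1)
        if p not in world.site_positions[u]
    ]
    lines = ["Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tHGVSp_Short"]
    for s in range(spec.n_samples):
        sample = f"SAMPLE_{s + 1}"
        n_on = int(round(spec.frac_on_sites * spec.muts_per_sample))
        n_off = spec.muts_per_sample - n_on
        replace = n_on > len(on_pool)
        if replace:
            logger.warning("on-site request %d exceeds %d site residues; sampling with replacement", n_on, len(on_pool))
        picks = [on_pool[k] for k in rng.choice(len(on_pool), size=n_on, replace=replace)]
        if n_off:
            off_replace = n_off > len(off_pool)
            picks += [off_pool[k] for k in rng.choice(len(off_pool), size=n_off, replace=off_replace)]
        for uid, pos in picks:
            ref, alt = _random_missense(rng, world.sequences[uid], pos)
            lines.append(
                f"{gene_of[uid]}\t{sample}\tMissense_Mutation\tp.{ref}{pos}{alt}"
            )
    out_path = Path(out_path)
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path


def gen_labeled_dataset(sep: SeparationSpec, schema: FeatureSchema | None = None) -> LabeledDataset:
    """Two-Gaussian labeled feature dataset with planted separation d-prime.

    Negatives are standard normal on the continuous features; positives are
    shifted by ``dprime`` pooled-sd units along a random unit direction in
    that subspace.  The one-hot site flags are assigned validly (exactly one
    flag set per row) independent of the label.
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(sep.seed)
    n = sep.n_pos + sep.n_neg
    d_cont = len(CONTINUOUS_INDICES)

    direction = rng.normal(size=d_cont)
    direction /= np.linalg.norm(direction)
    cont = rng.normal(size=(n, d_cont))
    cont[: sep.n_pos] += sep.dprime * direction

    X = np.zeros((n, len(schema)))
    X[:, list(CONTINUOUS_INDICES)] = cont
    flag_choice = rng.integers(0, len(FLAG_INDICES), size=n)
    for row, c in enumerate(flag_choice):
        X[row, FLAG_INDICES[c]] = 1.0
    y = np.concatenate([np.ones(sep.n_pos, dtype=int), np.zeros(sep.n_neg, dtype=int)])
    return LabeledDataset(X, y, schema.version)


def gen_benchmark_table(
    world: SiteWorld, n_driver: int, n_passenger: int, seed: int = 0
):
    """Synthetic driver/passenger label table over the world's site residues.

    Emulates the shape of curated benchmark sets (e.g. 24/197 or 73/582)
    without any curated content; every mutation sits on a site residue so
    the whole table is mappable.  Rows have unique mutation keys.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 2])
    uids = sorted(world.sequences)
    gene_of = {u: g for g, u in world.genes.items()}
    pool = [(u, p) for u in uids for p in sorted(world.site_positions[u])]
    rows = []
    used: set[tuple[str, int, str]] = set()
    n_total = n_driver + n_passenger
    while len(rows) < n_total:
        uid, pos = pool[int(rng.integers(0, len(pool)))]
        ref, alt = _random_missense(rng, world.sequences[uid], pos)
        key = (uid, pos, alt)
        if key in used:
            continue
        used.add(key)
        rows.append(
            {
                "uniprot_id": uid,
                "gene_symbol": gene_of[uid],
                "ref_aa": ref,
                "position": pos,
                "alt_aa": alt,
                "label": "driver" if len(rows) < n_driver else "passenger",
                "source": "synthetic",
            }
        )
    return pd.DataFrame(rows)


def write_label_table(df, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path
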