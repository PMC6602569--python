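"""Per-sample driver-protein ranking and the annotation summaries.

A sample's ranked target list carries one entry per qualifying driver
mutation (score strictly above threshold, mapped to a site), ordered by
score descending with ties broken by gene symbol then position.  A
protein's headline score is its best driver-mutation score.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .site_db import SiteDatabase
from .site_mapping import MappedMutation


@dataclass(frozen=True)
class TargetEntry:
    sample_id: str
    gene_symbol: str
    uniprot_id: str
    driver_mutation: str
    location: int
    area: str
    score: float


@dataclass(frozen=True)
class DomainOverlay:
    uniprot_id: str
    domains: tuple[tuple[str, int, int], ...]  # (name, start, end) 1-based inclusive
    positions: tuple[tuple[int, int, tuple[str, ...]], ...]  # (position, frequency, covering domains)


def _sort_key(e: TargetEntry):
    return (-e.score, e.gene_symbol, e.location)


def rank_targets(
    scored: list[tuple[MappedMutation, float]], threshold: float = 0.5
) -> dict[str, list[TargetEntry]]:
    """Build the per-sample ranked target lists from scored mutations.

    Only mutations with score strictly above the threshold qualify; the
    result is a pure, shuffle-invariant function of the prediction set.
    """
    per_sample: dict[str, list[TargetEntry]] = {}
    for mm, s in scored:
        if s <= threshold or mm.area == "OTHER":
            continue
        m = mm.mutation
        per_sample.setdefault(m.sample_id, []).append(
            TargetEntry(m.sample_id, m.gene_symbol, mm.uniprot_id, m.change, m.position, mm.area, s)
        )
    return {sid: sorted(v, key=_sort_key) for sid, v in sorted(per_sample.items())}


def score_profile(
    scored: list[tuple[MappedMutation, float]],
    sample_id: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """All scored site mutations of one sample, score-descending.

    Sub-threshold mutations are included and flagged (is_driver = 0) so the
    profile shows the full probability landscape, not only the calls.
    Raises for a sample that never appears in the prediction set.
    """
    known = {mm.mutation.sample_id for mm, _ in scored}
    if sample_id not in known:
        raise KeyError(f"unknown sample {sample_id!r}")
    rows = [
        {
            "gene_symbol": mm.mutation.gene_symbol,
            "uniprot_id": mm.uniprot_id,
            "mutation": mm.mutation.change,
            "area": mm.area,
            "score": s,
            "is_driver": int(s > threshold),
        }
        for mm, s in scored
        if mm.mutation.sample_id == sample_id
    ]
    df = pd.DataFrame(
        rows, columns=["gene_symbol", "uniprot_id", "mutation", "area", "score", "is_driver"]
    )
    if len(df):
        df = df.sort_values(
            by=["score", "gene_symbol", "mutation"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def pan_cancer_matrix(
    clinical_table: pd.DataFrame, db: SiteDatabase, uniprot_id: str
) -> pd.DataFrame:
    """Cancer-type x site-residue counts of clinical mutations for one protein.

    Rows are cancer types, columns the protein's active site residues that
    carry at least one mutation; cells are raw mutation counts.
    """
    if uniprot_id not in db.sites_by_protein:
        raise KeyError(f"protein {uniprot_id} absent from site database")
    site_res = db.active_residues(uniprot_id)
    sub = clinical_table[
        (clinical_table["uniprot_id"] == uniprot_id)
        & (clinical_table["position"].isin(site_res))
    ]
    if sub.empty:
        return pd.DataFrame()
    mat = (
        sub.groupby(["cancer_type", "position"]).size().unstack(fill_value=0)
    )
    mat = mat.reindex(sorted(mat.index), axis=0).reindex(sorted(mat.columns), axis=1)
    return mat


def load_domain_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    need = {"uniprot_id", "domain_name", "start", "end"}
    if missing := need - set(df.columns):
        raise ValueError(f"domain table missing columns {sorted(missing)}")
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise ValueError(f"inverted domain interval(s): {bad['domain_name'].tolist()}")
    return df


def domain_overlay(
    domain_table: pd.DataFrame,
    predictions: list[tuple[MappedMutation, float]],
    uniprot_id: str,
    threshold: float = 0.5,
) -> DomainOverlay:
    """Annotate predicted driver positions with covering domains.

    Intervals are 1-based inclusive on both ends; overlapping covering
    domains are all listed, ordered by start.  Per-position frequency is the
    cohort tally of qualifying driver mutations at that position.
    """
    doms = domain_table[domain_table["uniprot_id"] == uniprot_id]
    doms = doms.sort_values(["start", "end", "domain_name"])
    intervals = tuple(
        (r["domain_name"], int(r["start"]), int(r["end"])) for _, r in doms.iterrows()
    )
    freq: dict[int, int] = {}
    for mm, s in predictions:
        if mm.uniprot_id == uniprot_id and s > threshold and mm.area != "OTHER":
            freq[mm.mutation.position] = freq.get(mm.mutation.position, 0) + 1
    positions = tuple(
        (
            pos,
            n,
            tuple(name for name, a, b in intervals if a <= pos <= b) or ("none",),
        )
        for pos, n in sorted(freq.items())
    )
    return DomainOverlay(uniprot_id, intervals, positions)


def write_score_profile(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if len(out):
        out["score"] = out["score"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_pan_cancer_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", lineterminator="\n")


def write_domain_overlay(overlay: DomainOverlay, path) -> None:
    rows = [
        {
            "uniprot_id": overlay.uniprot_id,
            "position": pos,
            "frequency": n,
            "domains": ",".join(names),
        }
        for pos, n, names in overlay.positions
    ]
    pd.DataFrame(rows, columns=["uniprot_id", "position", "frequency", "domains"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
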