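"""Fixed-schema numeric featurization of site-mapped mutations.

The v1 schema is the package's declared descriptor set: three one-hot site
flags, two structural annotations carried by the residue table (relative
solvent accessibility and a flexibility proxy), and six physicochemical
substitution descriptors computed from standard residue property tables.
The schema is versioned so an alternative descriptor set can be added
without invalidating stored models; all model code is schema-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .site_db import SiteDatabase
from .site_mapping import MappedMutation


class FeaturizationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSchema:
    names: tuple[str, ...]
    version: str

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)


_V1_NAMES = (
    "is_allo_exp",
    "is_allo_pred",
    "is_ortho",
    "rsa",
    "flex",
    "d_hydropathy",
    "d_volume",
    "d_charge",
    "blosum62",
    "pro_introduced",
    "gly_lost",
)

#: Indices of the one-hot site flags within the v1 schema.
FLAG_INDICES = (0, 1, 2)
#: Indices of the continuous (non-flag) features within the v1 schema.
CONTINUOUS_INDICES = tuple(range(3, len(_V1_NAMES)))


def default_schema() -> FeatureSchema:
    return FeatureSchema(names=_V1_NAMES, version="v1")


# Kyte & Doolittle (1982) hydropathy index.
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Zamyatnin (1972) residue volumes, cubic angstroms.
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

# Formal side-chain charge at pH 7 (His taken as neutral).
FORMAL_CHARGE = {aa: 0.0 for aa in KD_HYDROPATHY}
FORMAL_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0})

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

_AREA_FLAGS = {
    "ALLO_EXP": (1.0, 0.0, 0.0),
    "ALLO_PRED": (0.0, 1.0, 0.0),
    "ORTHO": (0.0, 0.0, 1.0),
}


def featurize(mm: MappedMutation, db: SiteDatabase, schema: FeatureSchema | None = None) -> np.ndarray:
    """Build the feature vector for one site-mapped mutation.

    Only site mutations are scoreable; area OTHER raises.  A missing residue
    annotation for (protein, position) is an error naming both — the vector
    either completes with finite entries or featurization fails.
    """
    schema = schema or default_schema()
    if schema.version != "v1":
        raise FeaturizationError(f"unknown schema version {schema.version!r}")
    if mm.area == "OTHER":
        raise FeaturizationError(f"{mm.mutation.change}: area OTHER is not scoreable")
    m = mm.mutation
    ann = db.annotation(mm.uniprot_id, m.position)
    if ann is None:
        raise FeaturizationError(
            f"no residue annotation for {mm.uniprot_id} position {m.position}"
        )
    flags = _AREA_FLAGS[mm.area]
    ref, alt = m.ref_aa, m.alt_aa
    vec = np.array(
        [
            *flags,
            ann.rsa,
            ann.flex,
            KD_HYDROPATHY[alt] - KD_HYDROPATHY[ref],
            RESIDUE_VOLUME[alt] - RESIDUE_VOLUME[ref],
            FORMAL_CHARGE[alt] - FORMAL_CHARGE[ref],
            float(_BLOSUM62[ref, alt]),
            float(alt == "P" and ref != "P"),
            float(ref == "G" and alt != "G"),
        ],
        dtype=float,
    )
    if not np.all(np.isfinite(vec)):
        raise FeaturizationError(f"non-finite feature for {m.change}")
    return vec


def featurize_many(
    mapped: list[MappedMutation], db: SiteDatabase, schema: FeatureSchema | None = None
) -> tuple[np.ndarray, list[MappedMutation]]:
    """Featurize all scoreable mutations; returns (matrix, kept mutations)."""
    schema = schema or default_schema()
    rows, kept = [], []
    for mm in mapped:
        if not mm.scoreable:
            continue
        rows.append(featurize(mm, db, schema))
        kept.append(mm)
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(schema)))
    return X, kept


def export_feature_matrix(
    X: np.ndarray, mapped: list[MappedMutation], schema: FeatureSchema, path
) -> None:
    """Audit export: one schema-ordered row per featurized mutation."""
    df = pd.DataFrame(X, columns=list(schema.names))
    df.insert(0, "mutation", [mm.mutation.change for mm in mapped])
    df.insert(0, "uniprot_id", [mm.uniprot_id for mm in mapped])
    df.insert(0, "sample", [mm.mutation.sample_id for mm in mapped])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit z-scaling parameters on training vectors only.

    Population standard deviation; constant features get sd treated as 1 so
    scaling is a no-op for them.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    means = train.mean(axis=0)
    sds = train.std(axis=0)
    sds = np.where(sds == 0.0, 1.0, sds)
    return means, sds


def apply_standardization(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - means) / sds
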