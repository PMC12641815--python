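"""Descriptor matrices: binned EI spectra (+RI) and structure-derived features.

The *analytical descriptor* is the unit-mass binned full-scan spectrum over a
global m/z frame, optionally concatenated with the retention index; the
*molecular descriptors* are fingerprints/structure keys and continuous 2D
descriptors computed from SMILES.  Standardization conventions differ by
consumer: z-scored inputs for the embedding, raw intensities for the
tree-boosting models (trees are invariant to monotone per-feature scaling).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .spectra_io import Dataset, SpectrumRecord

logger = logging.getLogger(__name__)

MOLECULAR_KINDS = ("ecfp6", "maccs", "pubchem", "topological")
DESCRIPTOR_KINDS = ("analytical", "analytical_no_ri") + MOLECULAR_KINDS

#: continuous 2D descriptors standing in for a CDK-style topological set;
#: includes mass-derived features (MolWt, ExactMolWt) by design
TOPOLOGICAL_DESCRIPTOR_NAMES = (
    "MolWt",
    "ExactMolWt",
    "HeavyAtomCount",
    "NumAromaticRings",
    "NumAliphaticRings",
    "RingCount",
    "NumRotatableBonds",
    "NumHAcceptors",
    "NumHDonors",
    "FractionCSP3",
    "TPSA",
    "MolLogP",
    "BalabanJ",
    "BertzCT",
    "Chi0",
    "Chi1",
    "Kappa1",
    "Kappa2",
    "HallKierAlpha",
    "LabuteASA",
)


def nominal_mass(mz: float) -> int:
    """Round-half-up nominal mass of a measured m/z."""
    return math.floor(mz + 0.5)


@dataclass
class AnalyticalDescriptor:
    """Unit-width binned spectrum over [mz_min, mz_max] plus optional RI."""

    bin_intensities: np.ndarray
    mz_min: int
    mz_max: int
    ri: float | None = None

    def __post_init__(self) -> None:
        self.bin_intensities = np.asarray(self.bin_intensities, dtype=float)
        expected = self.mz_max - self.mz_min + 1
        if self.bin_intensities.shape != (expected,):
            raise ValueError(
                f"bin vector length {self.bin_intensities.shape} != {expected}"
            )

    @property
    def bin_mz(self) -> np.ndarray:
        return np.arange(self.mz_min, self.mz_max + 1, dtype=float)


@dataclass
class DescriptorMatrix:
    """compounds × features matrix with its standardization state."""

    matrix: np.ndarray
    feature_names: list[str]
    compound_ids: list[str]
    descriptor_kind: str
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    constant_columns: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.compound_ids), len(self.feature_names)):
            raise ValueError("matrix shape inconsistent with ids/feature names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.compound_ids, columns=self.feature_names
        )

    def rows_for(self, ids: list[str]) -> np.ndarray:
        index = {cid: i for i, cid in enumerate(self.compound_ids)}
        return self.matrix[[index[i] for i in ids]]

    def drop_ri_column(self) -> "DescriptorMatrix":
        """Spectrum-only view (for similarity computations)."""
        if "RI" not in self.feature_names:
            return self
        keep = [i for i, n in enumerate(self.feature_names) if n != "RI"]
        return DescriptorMatrix(
            matrix=self.matrix[:, keep],
            feature_names=[self.feature_names[i] for i in keep],
            compound_ids=list(self.compound_ids),
            descriptor_kind=self.descriptor_kind,
            standardized=self.standardized,
            provenance=self.provenance,
        )


def bin_spectrum(
    record: SpectrumRecord,
    mz_min: int,
    mz_max: int,
    base_peak_normalize: bool = True,
) -> AnalyticalDescriptor:
    """Assign peaks to round-half-up nominal bins; colliding peaks summed.

    With ``base_peak_normalize`` the vector is rescaled so its maximum is
    999 (library convention); otherwise total intensity is conserved.
    """
    vec = np.zeros(mz_max - mz_min + 1)
    for mz, inten in record.peaks:
        b = nominal_mass(mz)
        if b < mz_min or b > mz_max:
            raise ValueError(
                f"compound {record.compound_id!r}: peak at m/z {mz} outside "
                f"bin range [{mz_min}, {mz_max}]"
            )
        vec[b - mz_min] += inten
    if base_peak_normalize:
        vec *= 999.0 / vec.max()
    return AnalyticalDescriptor(vec, mz_min, mz_max, ri=record.ri)


def standardize_columns(
    matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column z-scoring; constant columns become all-zero and are flagged.

    Returns (standardized matrix, means, sds, constant-column mask).  Sample
    standard deviation (ddof=1) is used so a standardized column has unit
    sample variance.  Idempotent within 1e-9 on already-standardized input.
    """
    matrix = np.asarray(matrix, dtype=float)
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros(matrix.shape[1])
    constant = sds <= 1e-12
    out = np.zeros_like(matrix)
    nz = ~constant
    out[:, nz] = (matrix[:, nz] - means[nz]) / sds[nz]
    return out, means, sds, constant


def build_analytical_matrix(
    dataset: Dataset,
    include_ri: bool = True,
    standardize: bool = False,
    base_peak_normalize: bool = True,
) -> DescriptorMatrix:
    """Binned-spectrum matrix over the dataset's global m/z frame.

    Records lacking an RI are dropped (and counted in the log) when
    ``include_ri`` is requested.  Columns are the unit-mass bins, with an
    ``RI`` column appended last when included.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    records = list(dataset.records)
    if include_ri:
        kept = [r for r in records if r.ri is not None]
        if len(kept) < len(records):
            logger.info(
                "build_analytical_matrix: dropped %d records lacking RI",
                len(records) - len(kept),
            )
        records = kept
        if not records:
            raise ValueError("no records with RI available")
    lo, hi = dataset.global_mz_range
    rows = [
        bin_spectrum(r, lo, hi, base_peak_normalize=base_peak_normalize).bin_intensities
        for r in records
    ]
    matrix = np.vstack(rows)
    names = [f"mz_{m}" for m in range(lo, hi + 1)]
    if include_ri:
        matrix = np.hstack([matrix, np.array([[r.ri] for r in records])])
        names = names + ["RI"]
    kind = "analytical" if include_ri else "analytical_no_ri"
    result = DescriptorMatrix(
        matrix=matrix,
        feature_names=names,
        compound_ids=[r.compound_id for r in records],
        descriptor_kind=kind,
    )
    if standardize:
        std, means, sds, constant = standardize_columns(result.matrix)
        result.matrix = std
        result.standardized = True
        result.column_means, result.column_sds = means, sds
        result.constant_columns = constant
    return result


def _mol_features(mol: Chem.Mol, kind: str, ecfp_bits: int) -> np.ndarray:
    if kind == "ecfp6":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=ecfp_bits)
        return np.array(gen.GetFingerprint(mol), dtype=float)
    if kind == "maccs":
        # toolkit emits 167 bits with bit 0 unused; drop it for the 166-bit key
        return np.array(MACCSkeys.GenMACCSKeys(mol), dtype=float)[1:]
    if kind == "pubchem":
        # 881-bit substructure-key stand-in (pattern fingerprint hashed to 881)
        fp = Chem.PatternFingerprint(mol, fpSize=881)
        return np.array(fp, dtype=float)
    if kind == "topological":
        return np.array(
            [getattr(RDDescriptors, n)(mol) for n in TOPOLOGICAL_DESCRIPTOR_NAMES],
            dtype=float,
        )
    raise ValueError(f"unknown molecular descriptor kind {kind!r}")


def build_molecular_matrix(
    dataset: Dataset,
    kind: str,
    standardize_continuous: bool = False,
    ecfp_bits: int = 1024,
) -> DescriptorMatrix:
    """Structure-derived matrix of the requested kind from record SMILES.

    Records without parseable SMILES are dropped with a logged count.
    ``standardize_continuous`` z-scores the (continuous) topological matrix;
    it is ignored for bit-vector kinds.
    """
    if kind not in MOLECULAR_KINDS:
        raise ValueError(f"unknown molecular descriptor kind {kind!r}")
    ids, rows = [], []
    n_dropped = 0
    for rec in dataset:
        mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        if mol is None:
            n_dropped += 1
            continue
        ids.append(rec.compound_id)
        rows.append(_mol_features(mol, kind, ecfp_bits))
    if n_dropped:
        logger.info(
            "build_molecular_matrix(%s): dropped %d records without parseable SMILES",
            kind,
            n_dropped,
        )
    if not rows:
        raise ValueError("no records with parseable SMILES")
    matrix = np.vstack(rows)
    if kind == "ecfp6":
        names = [f"ecfp6_{i}" for i in range(ecfp_bits)]
    elif kind == "maccs":
        names = [f"maccs_{i}" for i in range(1, 167)]
    elif kind == "pubchem":
        names = [f"pc_{i}" for i in range(881)]
    else:
        names = list(TOPOLOGICAL_DESCRIPTOR_NAMES)
    result = DescriptorMatrix(
        matrix=matrix,
        feature_names=names,
        compound_ids=ids,
        descriptor_kind=kind,
        provenance="pubchem_fallback(rdkit-pattern-881)" if kind == "pubchem" else "rdkit",
    )
    if standardize_continuous and kind == "topological":
        std, means, sds, constant = standardize_columns(result.matrix)
        result.matrix = std
        result.standardized = True
        result.column_means, result.column_sds = means, sds
        result.constant_columns = constant
    return result


def build_matrix(dataset: Dataset, kind: str, standardize: bool = False) -> DescriptorMatrix:
    """Dispatch over every descriptor kind (CLI convenience)."""
    if kind == "analytical":
        return build_analytical_matrix(dataset, include_ri=True, standardize=standardize)
    if kind == "analytical_no_ri":
        return build_analytical_matrix(dataset, include_ri=False, standardize=standardize)
    return build_molecular_matrix(dataset, kind, standardize_continuous=standardize)


def tanimoto(u: np.ndarray, v: np.ndarray) -> float:
    """Tanimoto coefficient of two binary fingerprint vectors."""
    u = np.asarray(u) > 0
    v = np.asarray(v) > 0
    union = np.logical_or(u, v).sum()
    if union == 0:
        raise ValueError("both fingerprints empty")
    return float(np.logical_and(u, v).sum() / union)
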