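"""Expression studies, delta z-scores and per-gene significance calls.

The central quantity is the delta z-score of gene *j* in a treated sample
*i*: the gene is z-transformed across *all* samples of the study and the
z-transformed vehicle (DMSO) control is subtracted,

    Z_ij = (X_ij - mu_j) / sigma_j - (X_DMSO,j - mu_j) / sigma_j

so Z_ij measures how far, in gene-level standard deviations, the treated
expression sits from the control. A gene is called significantly changed
when the two-sided standard-normal tail probability of its delta z-score
falls strictly below ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInfo",
    "ExpressionStudy",
    "DeltaZProfile",
    "load_expression",
    "read_sample_metadata",
    "delta_z",
    "gene_significance",
]


@dataclass(frozen=True)
class SampleInfo:
    """Annotation of one expression column: which drug, dose, control flag."""

    sample_id: str
    drug: str
    concentration: str
    is_control: bool


@dataclass
class ExpressionStudy:
    """A normalized genes x samples expression matrix with sample metadata.

    ``values`` is indexed by gene identifier with one column per sample, in
    the order of ``samples``. Loading guarantees unique gene identifiers, at
    least one control column, a drug name on every treated column and no
    missing values.
    """

    values: pd.DataFrame
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("sample metadata order does not match matrix columns")
        if self.values.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        if not any(s.is_control for s in self.samples):
            raise ValueError("study has no control (vehicle) sample")
        for s in self.samples:
            if not s.is_control and not s.drug:
                raise ValueError(f"treated sample {s.sample_id!r} has no drug name")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def control_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.is_control]

    @property
    def treated(self) -> list[SampleInfo]:
        return [s for s in self.samples if not s.is_control]

    def sample(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"unknown sample id {sample_id!r}")

    def zscores(self, std_mode: str = "sample") -> tuple[pd.DataFrame, pd.Index]:
        """Row-wise z-transform of the matrix over all samples.

        Returns the z-score matrix restricted to genes with positive
        standard deviation, plus the index of dropped (zero-variance) genes.
        ``std_mode`` selects the n-1 ("sample", default) or n ("population")
        denominator.
        """
        if std_mode not in ("sample", "population"):
            raise ValueError(f"std_mode must be 'sample' or 'population', got {std_mode!r}")
        ddof = 1 if std_mode == "sample" else 0
        mu = self.values.mean(axis=1)
        sigma = self.values.std(axis=1, ddof=ddof)
        dropped = self.values.index[~(sigma > 0)]
        if len(dropped):
            logger.info("dropping %d zero-variance genes from z-transform", len(dropped))
        keep = sigma > 0
        z = self.values.loc[keep].sub(mu[keep], axis=0).div(sigma[keep], axis=0)
        return z, dropped


@dataclass
class DeltaZProfile:
    """Per-gene delta z-scores of one treated sample versus the control."""

    drug: str
    concentration: str
    genes: pd.Index
    z: np.ndarray
    significant: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.genes) != self.z.shape[0]:
            raise ValueError("z vector length does not match gene index")

    @property
    def significant_genes(self) -> frozenset[str]:
        if self.significant is None:
            raise ValueError("call gene_significance() before reading significant_genes")
        return frozenset(self.genes[self.significant])

    def as_series(self) -> pd.Series:
        return pd.Series(self.z, index=self.genes, name=self.sample_id or self.drug)


def read_sample_metadata(path: str | Path) -> dict[str, SampleInfo]:
    """Read a 4-column TSV (sample_id, drug, concentration, is_control)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "drug", "concentration", "is_control"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file lacks columns: {sorted(missing)}")
    out: dict[str, SampleInfo] = {}
    truthy = {"1", "true", "yes", "y"}
    for row in meta.itertuples(index=False):
        out[row.sample_id] = SampleInfo(
            sample_id=row.sample_id,
            drug=row.drug,
            concentration=row.concentration,
            is_control=str(row.is_control).strip().lower() in truthy,
        )
    return out


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV, or GCT 1.2 (two-line header, NAME/Description)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2)
        df = df.drop(columns=["Description"], errors="ignore")
        df = df.set_index(df.columns[0])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def load_expression(
    path: str | Path,
    metadata: str | Path | dict[str, SampleInfo],
) -> ExpressionStudy:
    """Load an expression matrix plus sample annotations into a study.

    Rows with any missing value are dropped (logged); duplicate gene rows
    are collapsed by their mean (logged). A sample column without metadata,
    or a metadata table without any control sample, is a hard error.
    """
    df = _read_matrix(path)
    if isinstance(metadata, (str, Path)):
        metadata = read_sample_metadata(metadata)

    for col in df.columns:
        if col not in metadata:
            raise ValueError(f"sample column {col!r} has no metadata entry")

    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        logger.warning("dropping %d gene rows with missing values", n_na)
        df = df.dropna(axis=0)

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicated gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()

    samples = [metadata[c] for c in df.columns]
    return ExpressionStudy(values=df, samples=samples)


def delta_z(
    study: ExpressionStudy,
    sample_id: str,
    control_id: str | Sequence[str] | None = None,
    std_mode: str = "sample",
) -> DeltaZProfile:
    """Delta z-score profile of one sample against the vehicle control.

    ``control_id`` may name a single control column, several (their
    z-transformed values are averaged before subtraction), or be None to use
    every flagged control sample of the study. Genes whose standard
    deviation over all samples is zero are dropped from the profile.
    """
    info = study.sample(sample_id)
    z, _ = study.zscores(std_mode=std_mode)
    if control_id is None:
        controls = study.control_ids
    elif isinstance(control_id, str):
        controls = [control_id]
    else:
        controls = list(control_id)
    for c in controls:
        study.sample(c)  # raises on unknown id
    if len(controls) > 1:
        logger.info("averaging z-transformed values of %d control samples", len(controls))
    zc = z[controls].mean(axis=1)
    dz = (z[sample_id] - zc).to_numpy()
    return DeltaZProfile(
        drug=info.drug,
        concentration=info.concentration,
        genes=z.index,
        z=dz,
        sample_id=sample_id,
    )


def gene_significance(
    profile: DeltaZProfile,
    alpha: float = 0.05,
    null_variance: float = 1.0,
) -> DeltaZProfile:
    """Flag genes whose delta z-score is significant under a normal null.

    The two-sided p-value of ``z`` under N(0, null_variance) must be
    strictly below ``alpha``. ``null_variance=1`` treats the delta z-score
    itself as standard normal (|z| >= 1.96 at alpha 0.05);
    ``null_variance=2`` models it as the difference of two independent
    standard normals.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if null_variance <= 0:
        raise ValueError("null_variance must be positive")
    p = 2.0 * stats.norm.sf(np.abs(profile.z) / np.sqrt(null_variance))
    return replace(profile, significant=p < alpha)
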