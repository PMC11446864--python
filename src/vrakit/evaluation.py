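"""Reconstruction-accuracy evaluation and summary statistics.

A reconstruction is assessed against the intact reference bone exactly as
in the laboratory comparison of virtual and physical re-association: the
reconstructed cloud is ICP-registered onto the intact cloud, per-point
cloud-to-cloud distances are computed, and their mean (and RMS) summarise
accuracy.  Coverage — the fraction of the intact surface within a
tolerance of the reconstruction — decides whether a reconstruction counts
as "full" (the >95% criterion).  Paired series from the two methods are
compared with the Pearson product-moment correlation, with one-way and
two-way intraclass variants available as labelled alternatives.
"""

from __future__ import annotations

import dataclasses
import decimal
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointCloud, apply_transform, nearest_distances
from .registration import IcpParams, IcpResult, RigidTransform, icp_refine

__all__ = [
    "ReassemblyMetrics",
    "SummaryStats",
    "register_and_compare",
    "coverage",
    "summary_stats",
    "paired_correlation",
    "intraclass_correlation",
    "round_half_up",
]

#: default coverage tolerance in mm (the full-reconstruction criterion
#: names no tolerance; 2 mm is a few CT voxels)
DEFAULT_COVERAGE_EPSILON = 2.0

#: coverage above which a reconstruction counts as full
FULL_RECONSTRUCTION_COVERAGE = 0.95


@dataclasses.dataclass
class ReassemblyMetrics:
    """Accuracy and bookkeeping for one reconstructed bone.

    ``mean_distance`` is the statistic tabulated as reconstruction
    accuracy (μ); ``rms_distance`` is reported alongside because the two
    are easily conflated and RMS >= mean always.  ``reconstruction_time``
    is recorded externally by the operator, never measured here.
    """

    mean_distance: float
    rms_distance: float
    coverage: float
    n_fragments_total: int
    n_reassociated: int
    reconstruction_time_min: Optional[float] = None
    registration: Optional[IcpResult] = None

    def __post_init__(self) -> None:
        if self.n_reassociated > self.n_fragments_total:
            raise ValueError("n_reassociated cannot exceed n_fragments_total")

    @property
    def full_reconstruction(self) -> bool:
        return self.coverage > FULL_RECONSTRUCTION_COVERAGE


def register_and_compare(
    recon: PointCloud,
    intact: PointCloud,
    icp_params: Optional[IcpParams] = None,
    init: Optional[RigidTransform] = None,
    n_fragments_total: int = 0,
    n_reassociated: int = 0,
) -> tuple[np.ndarray, ReassemblyMetrics]:
    """Register a reconstruction onto its intact reference and measure it.

    Distances run reconstruction -> intact (each reconstructed point to
    its nearest intact point): reconstruction error is the question.  The
    per-point distances are returned so they can be exported as a scalar
    field for colorimetric inspection.
    """
    if icp_params is None:
        # evaluation registration: generous gate, light trimming
        icp_params = IcpParams(max_corr_dist=25.0, trim_keep_fraction=0.9)
    icp = icp_refine(intact, recon, init=init, params=icp_params)
    registered = apply_transform(recon, icp.transform)
    d = nearest_distances(registered, intact)
    cov = coverage(registered, intact)
    metrics = ReassemblyMetrics(
        mean_distance=float(d.mean()),
        rms_distance=float(np.sqrt(np.mean(d**2))),
        coverage=cov,
        n_fragments_total=n_fragments_total,
        n_reassociated=n_reassociated,
        registration=icp,
    )
    return d, metrics


def coverage(
    recon: PointCloud, intact: PointCloud, epsilon: float = DEFAULT_COVERAGE_EPSILON
) -> float:
    """Fraction of intact points with a reconstruction point within epsilon.

    The clouds must already be registered in a common frame.
    """
    tree = cKDTree(recon.points)
    d, _ = tree.query(intact.points, workers=-1)
    return float(np.mean(d <= epsilon))


@dataclasses.dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    min: float
    max: float
    n: int


def summary_stats(values) -> SummaryStats:
    """Mean, sample SD (n−1), min, max of a series.

    Stored values are never rounded; use :func:`round_half_up` for
    presentation at a chosen precision.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summary_stats of an empty series")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return SummaryStats(
        mean=float(v.mean()), sd=sd, min=float(v.min()), max=float(v.max()), n=int(v.size)
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding for presentation (2.5 -> 3, not banker's)."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def paired_correlation(x, y) -> float:
    """Pearson product-moment correlation of two paired series.

    This is the estimator that reproduces the published coefficients for
    paired virtual-vs-physical series; intraclass variants are available
    through :func:`intraclass_correlation` for comparison.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(np.corrcoef(x, y)[0, 1])


def intraclass_correlation(x, y, form: str = "oneway") -> float:
    """Intraclass correlation of two paired raters, single-measure forms.

    ``oneway``
        ICC(1,1): one-way random effects — raters are not a factor.
    ``twoway``
        ICC(C,1): two-way mixed, consistency — rater means removed.
    ``agreement``
        ICC(A,1): two-way random, absolute agreement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    n, k = x.size, 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    ms_within = (ss_total - ss_rows) / (n * (k - 1))
    if form == "oneway":
        return float((ms_rows - ms_within) / (ms_rows + (k - 1) * ms_within))
    if form == "twoway":
        return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))
    if form == "agreement":
        return float(
            (ms_rows - ms_err)
            / (ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err))
        )
    raise ValueError(f"unknown ICC form: {form!r}")
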