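"""Correspondence-error evaluation and the dissociation report.

Registration accuracy is the distance between the estimated and the true
transformation, ``||T - T_true||`` -- not the similarity of the reformatted
image to the fixed image.  Here the truth is multi-valued: at duplicated
pixels (region A) two displacements are equally correct, so the pointwise
error is the minimum Euclidean distance from the estimate to the admissible
set; at overwritten pixels (region C) correspondence is undefined and the
pixel is excluded from every aggregate.

The dissociation report runs several registration methods on one scene and
compares, per method, the similarity triple of its reformatted image with
its correspondence-error summary.  A method whose similarity rank and
correspondence rank disagree is flagged as *dissociated* -- the failure mode
that similarity-only evaluation cannot detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .metrics import SimilarityTriple, similarity_report
from .registration import (
    CurtRegistration,
    IdentityRegistration,
    OracleRegistration,
    _check_field,
)
from .scenes import AdmissibleTruth

__all__ = [
    "CorrespondenceErrorSummary",
    "DissociationReport",
    "pointwise_error",
    "error_map",
    "summarize_errors",
    "dissociation_report",
    "EXCLUDED",
]

#: sentinel returned by :func:`pointwise_error` where correspondence is undefined
EXCLUDED = None


def pointwise_error(estimate, truth_set):
    """Displacement error of one estimated vector against an admissible set.

    Returns the minimum Euclidean distance from ``estimate`` to any vector
    in ``truth_set`` (a multi-valued truth scores its best admissible
    match), or :data:`EXCLUDED` (``None``) when the set is empty, i.e. the
    true correspondence is undefined at this pixel.
    """
    ux, uy = float(estimate[0]), float(estimate[1])
    if not (math.isfinite(ux) and math.isfinite(uy)):
        raise ValueError(f"non-finite displacement estimate {estimate!r}")
    truth_set = tuple(truth_set)
    if not truth_set:
        return EXCLUDED
    return min(math.hypot(ux - tx, uy - ty) for tx, ty in truth_set)


def error_map(displacement_field, truth: AdmissibleTruth) -> np.ndarray:
    """Per-pixel displacement error; NaN where correspondence is undefined."""
    fld = _check_field(displacement_field)
    if fld.shape[:2] != truth.shape:
        raise ValueError(f"field grid {fld.shape[:2]} != truth grid {truth.shape}")
    err = np.full(truth.shape, np.nan)
    for lab in "ABCD":
        mask = truth.region_mask(lab)
        admissible = truth.admissible(lab)
        if not admissible or not mask.any():
            continue
        du = fld[mask]  # (n, 2)
        dists = [
            np.hypot(du[:, 0] - tx, du[:, 1] - ty) for tx, ty in admissible
        ]
        err[mask] = np.min(dists, axis=0)
    return err


@dataclass(frozen=True)
class CorrespondenceErrorSummary:
    """Aggregate displacement error over pixels with defined correspondence."""

    n_evaluated: int
    n_excluded: int
    mean_error: float
    median_error: float
    max_error: float
    fraction_correct: float
    tolerance: float
    per_region: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
            "mean_error": self.mean_error,
            "median_error": self.median_error,
            "max_error": self.max_error,
            "fraction_correct": self.fraction_correct,
            "tolerance": self.tolerance,
            "per_region": self.per_region,
        }


def summarize_errors(displacement_field, truth: AdmissibleTruth,
                     tolerance: float = 0.5) -> CorrespondenceErrorSummary:
    """Summarize displacement errors against the admissible ground truth.

    Region C (empty admissible set) is excluded from all aggregates; its
    pixel count is reported as ``n_excluded``.  ``fraction_correct`` is the
    share of evaluated pixels with error at or below ``tolerance`` (default
    0.5 px, the sub-pixel rounding bound).  Per-region (A/B/D) breakdowns of
    count, mean error and fraction-correct are included.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    err = error_map(displacement_field, truth)
    defined = ~np.isnan(err)
    vals = err[defined]
    n_eval = int(defined.sum())
    n_excl = err.size - n_eval

    per_region = {}
    for lab in "ABD":
        mask = truth.region_mask(lab)
        if not mask.any():
            continue
        v = err[mask]
        per_region[lab] = {
            "n": int(mask.sum()),
            "mean_error": float(v.mean()),
            "max_error": float(v.max()),
            "fraction_correct": float((v <= tolerance).mean()),
        }

    return CorrespondenceErrorSummary(
        n_evaluated=n_eval,
        n_excluded=n_excl,
        mean_error=float(vals.mean()) if n_eval else float("nan"),
        median_error=float(np.median(vals)) if n_eval else float("nan"),
        max_error=float(vals.max()) if n_eval else float("nan"),
        fraction_correct=float((vals <= tolerance).mean()) if n_eval else float("nan"),
        tolerance=tolerance,
        per_region=per_region,
    )


@dataclass
class DissociationReport:
    """Per-method similarity and correspondence results, with rankings.

    ``similarity_rank`` ranks methods by their similarity triple (consensus
    of the three per-metric ranks; 1 = most similar); ``correspondence_rank``
    ranks by fraction-correct, ties broken by mean error (1 = most
    accurate).  ``dissociated`` lists the methods whose two ranks disagree
    -- evidence that image similarity misorders registration quality.
    """

    methods: list
    similarity: dict
    correspondence: dict
    similarity_rank: dict
    correspondence_rank: dict
    dissociated: list

    def as_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "similarity": {m: t.as_dict() for m, t in self.similarity.items()},
            "correspondence": {m: s.as_dict() for m, s in self.correspondence.items()},
            "similarity_rank": dict(self.similarity_rank),
            "correspondence_rank": dict(self.correspondence_rank),
            "dissociated": list(self.dissociated),
        }


def _builtin_methods(truth: AdmissibleTruth) -> dict:
    return {
        "curt": CurtRegistration(),
        "identity": IdentityRegistration(),
        "oracle": OracleRegistration(truth=truth),
    }


def dissociation_report(fixed, moving, truth: AdmissibleTruth,
                        methods=("curt", "identity"), tolerance: float = 0.5,
                        bin_width: float = 1.0, base: float = 2.0) -> DissociationReport:
    """Run registration methods on one scene and rank them both ways.

    ``methods`` is either a sequence of built-in names (``"curt"``,
    ``"identity"``, ``"oracle"``) or a mapping of name -> unfitted estimator
    with the ``fit(fixed, moving)`` / ``transform(moving)`` protocol.
    """
    if isinstance(methods, dict):
        estimators = dict(methods)
    else:
        builtins = _builtin_methods(truth)
        unknown = [m for m in methods if m not in builtins]
        if unknown:
            raise ValueError(f"unknown built-in methods {unknown}; "
                             f"choose from {sorted(builtins)}")
        estimators = {m: builtins[m] for m in methods}
    if not estimators:
        raise ValueError("at least one method is required")

    names = list(estimators)
    similarity: dict[str, SimilarityTriple] = {}
    correspondence: dict[str, CorrespondenceErrorSummary] = {}
    for name, est in estimators.items():
        est.fit(fixed, moving)
        reformatted = est.transform(moving)
        similarity[name] = similarity_report(
            fixed, reformatted, bin_width=bin_width, base=base
        )
        correspondence[name] = summarize_errors(
            est.displacement_field_, truth, tolerance=tolerance
        )

    # similarity consensus rank: average the per-metric ranks, then re-rank
    metric_ranks = []
    for metric, direction in SimilarityTriple.DIRECTIONS.items():
        vals = np.array([getattr(similarity[m], metric) for m in names])
        metric_ranks.append(rankdata(-direction * vals, method="average"))
    sim_rank = rankdata(np.mean(metric_ranks, axis=0), method="average")

    frac = np.array([correspondence[m].fraction_correct for m in names])
    mean_err = np.array([correspondence[m].mean_error for m in names])
    corr_rank = rankdata(
        rankdata(-frac, method="average") + 1e-9 * rankdata(mean_err, method="average"),
        method="average",
    )

    similarity_rank = {m: float(r) for m, r in zip(names, sim_rank)}
    correspondence_rank = {m: float(r) for m, r in zip(names, corr_rank)}
    dissociated = [
        m for m in names if similarity_rank[m] != correspondence_rank[m]
    ]
    return DissociationReport(
        methods=names,
        similarity=similarity,
        correspondence=correspondence,
        similarity_rank=similarity_rank,
        correspondence_rank=correspondence_rank,
        dissociated=dissociated,
    )
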