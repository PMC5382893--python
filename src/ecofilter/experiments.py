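"""Reproducible experiment protocols for the false-negative detection method.

Four runners, each returning a structured :class:`ExperimentReport`:

* ``imputation_experiment`` — LOO-impute every cell, compare positive vs
  negative scores (AUC, ROC, precision@k).
* ``fn_recovery_experiment`` — flip each positive to zero in turn and check
  whether its LOO score still outranks the true negatives.
* ``robustness_sweep`` — plant growing fractions of false negatives and
  compare the linear filter against the low-rank SVD baseline.
* ``forbidden_links_experiment`` — when true negatives are known, split the
  negative side into forbidden and potential false negatives.

Every stochastic run records its seed and reruns reproduce results exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import auc, precision_at_k, roc_curve
from .linear_filter import (
    DEFAULT_PARAMS,
    FilterParams,
    LinearFilter,
    loo_impute_all,
)
from .matrix_io import ForbiddenMask, InteractionMatrix, binarize, density
from .svd_baseline import SVDReestimator

__all__ = [
    "ExperimentReport",
    "imputation_experiment",
    "fn_recovery_experiment",
    "robustness_sweep",
    "forbidden_links_experiment",
    "catalogue_summary",
]

DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.50, 0.90)
DEFAULT_REPEATS = 100

DENSITY_BINS = ((0.0, 0.1), (0.1, 0.25), (0.25, 1.0))
COUNT_BINS = ((0, 50), (50, 100), (100, 1000), (1000, 10000), (10000, float("inf")))


@dataclasses.dataclass
class ExperimentReport:
    """Structured result of one experiment run.

    ``results`` is experiment-specific; ``provenance`` isolates the
    timestamp in a single field so that determinism checks can ignore it.
    """

    experiment: str
    dataset: str
    params: dict
    variant: str
    seed: int | None
    results: dict
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = {
                "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                "version": __version__,
            }

    def to_dict(self) -> dict:
        return _jsonify(dataclasses.asdict(self))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def flat_table(self) -> pd.DataFrame:
        """Flat key/value view of scalar results for TSV export."""
        rows = []

        def walk(prefix: str, obj) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (int, float, str, bool)) or obj is None:
                rows.append({"key": prefix, "value": obj})

        walk("", self.results)
        return pd.DataFrame(rows, columns=["key", "value"])

    def to_tsv(self, path: str | Path) -> None:
        self.flat_table().to_csv(path, sep="\t", index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _params_dict(params: FilterParams, **extra) -> dict:
    d = {
        "alpha1": params.alpha1,
        "alpha2": params.alpha2,
        "alpha3": params.alpha3,
        "alpha4": params.alpha4,
    }
    d.update(extra)
    return d


def _prepare(matrix: InteractionMatrix, binarize_first: bool) -> InteractionMatrix:
    return binarize(matrix) if binarize_first else matrix


def imputation_experiment(
    matrix: InteractionMatrix,
    params: FilterParams | None = None,
    binarize_first: bool = False,
) -> ExperimentReport:
    """Score every cell by LOO imputation; AUC of positives vs negatives.

    Also reports the ROC curve and precision@k for k in {10, 20, 50, 100}
    (clipped to the matrix size).
    """
    p = params or DEFAULT_PARAMS
    work = _prepare(matrix, binarize_first)
    pos_mask = work.positive_mask
    if not pos_mask.any() or pos_mask.all():
        raise ValueError("AUC undefined: matrix needs at least one positive and one negative")
    scores = loo_impute_all(work, p)
    pos = scores.scores[pos_mask]
    neg = scores.scores[~pos_mask]
    roc = roc_curve(pos, neg)
    ks = [k for k in (10, 20, 50, 100) if 1 <= k <= work.values.size]
    precision = {str(k): precision_at_k(work, scores, k) for k in ks}
    return ExperimentReport(
        experiment="imputation",
        dataset=matrix.name,
        params=_params_dict(p),
        variant="binarized" if binarize_first else "raw",
        seed=None,
        results={
            "auc": auc(pos, neg),
            "n_pos": int(pos.size),
            "n_neg": int(neg.size),
            "density": density(work),
            "precision_at_k": precision,
            "roc_points": roc.points,
        },
    )


def fn_recovery_experiment(
    matrix: InteractionMatrix,
    params: FilterParams | None = None,
    binarize_first: bool = False,
) -> ExperimentReport:
    """Flip-one-positive recovery: can a single hidden link be re-found?

    For each positive cell p a variant matrix is built with p set to zero and
    *all* zero cells of the variant are LOO-scored (the flip shifts row,
    column and total sums, so every score changes).  The per-flip AUC is the
    fraction of the original true-negative cells scoring strictly below p,
    plus half credit per tie.  The dataset's recovery AUC is the mean of the
    per-flip AUCs; a pooled AUC over all flips is reported alongside.
    """
    p = params or DEFAULT_PARAMS
    work = _prepare(matrix, binarize_first)
    values = work.values
    pos_cells = np.argwhere(values > 0)
    neg_mask = values == 0
    if len(pos_cells) == 0:
        raise ValueError("no positive interactions to flip")
    if not neg_mask.any():
        raise ValueError("no true negatives to compare against")

    est = LinearFilter(*p.as_tuple(), mode="loo").fit(values)
    per_flip = []
    flip_scores = []
    pooled_neg = []
    for i, j in pos_cells:
        variant = values.copy()
        variant[i, j] = 0.0
        scores = est.transform(variant)
        s_flip = scores[i, j]
        tn_scores = scores[neg_mask]
        per_flip.append(auc([s_flip], tn_scores))
        flip_scores.append(float(s_flip))
        pooled_neg.append(tn_scores)

    pooled_auc = auc(flip_scores, np.concatenate(pooled_neg))
    return ExperimentReport(
        experiment="fn_recovery",
        dataset=matrix.name,
        params=_params_dict(p),
        variant="binarized" if binarize_first else "raw",
        seed=None,
        results={
            "recovery_auc": float(np.mean(per_flip)),
            "recovery_auc_std": float(np.std(per_flip)),
            "pooled_auc": float(pooled_auc),
            "n_flips": len(per_flip),
            "per_flip_auc": [float(a) for a in per_flip],
            "density": density(work),
            "n_pos": int(len(pos_cells)),
        },
    )


def robustness_sweep(
    matrix: InteractionMatrix,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    params: FilterParams | None = None,
    svd_threshold: float = 0.75,
    binarize_first: bool = False,
) -> ExperimentReport:
    """Plant false negatives at several rates; filter vs SVD baseline.

    Per fraction and repetition, round(fraction * #positives) positives (at
    least 1) are zeroed; the zero cells of the degraded matrix are scored by
    (a) the LOO linear filter and (b) SVD re-estimation at the
    variance-retention rank, and each method's AUC separates the planted
    false negatives from the original true negatives.  Repetition seeds are
    shared across fractions (the removal sets are nested), so fraction
    curves are paired.
    """
    p = params or DEFAULT_PARAMS
    work = _prepare(matrix, binarize_first)
    values = work.values
    pos_cells = np.argwhere(values > 0)
    n_pos = len(pos_cells)
    neg_mask = values == 0
    if n_pos < 2:
        raise ValueError("need at least 2 positives for a robustness sweep")
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError(f"fractions must be in (0, 1), got {f}")
        if int(round(f * n_pos)) >= n_pos:
            raise ValueError(f"fraction {f} would remove all {n_pos} positives")

    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(n_repeats)
    filter_est = LinearFilter(*p.as_tuple(), mode="loo").fit(values)

    table = []  # rows: fraction, repeat, method, auc
    for frac in fractions:
        k = max(1, int(round(frac * n_pos)))
        for r in range(n_repeats):
            rng = np.random.default_rng(repeat_seeds[r])
            perm = rng.permutation(n_pos)
            removed = pos_cells[perm[:k]]
            degraded = values.copy()
            degraded[removed[:, 0], removed[:, 1]] = 0.0

            planted_idx = (removed[:, 0], removed[:, 1])
            filt_scores = filter_est.transform(degraded)
            table.append(
                {
                    "fraction": frac,
                    "repeat": r,
                    "method": "filter",
                    "auc": auc(filt_scores[planted_idx], filt_scores[neg_mask]),
                }
            )
            svd = SVDReestimator(threshold=svd_threshold).fit(degraded)
            svd_scores = svd.transform(degraded)
            table.append(
                {
                    "fraction": frac,
                    "repeat": r,
                    "method": "svd",
                    "auc": auc(svd_scores[planted_idx], svd_scores[neg_mask]),
                    "rank": svd.rank_,
                }
            )

    df = pd.DataFrame(table)
    summary = (
        df.groupby(["fraction", "method"])["auc"].agg(["mean", "std"]).reset_index()
    )
    return ExperimentReport(
        experiment="robustness",
        dataset=matrix.name,
        params=_params_dict(p, svd_threshold=svd_threshold),
        variant="binarized" if binarize_first else "raw",
        seed=seed,
        results={
            "fractions": list(fractions),
            "n_repeats": n_repeats,
            "summary": summary.to_dict(orient="records"),
            "table": table,
        },
    )


def forbidden_links_experiment(
    matrix: InteractionMatrix,
    forbidden: ForbiddenMask,
    params: FilterParams | None = None,
    n_hist_bins: int = 20,
) -> ExperimentReport:
    """Score all cells; split negatives into forbidden and potential FNs.

    Reports three AUCs: positives vs all negatives, positives vs forbidden
    (true negatives) only, and positives vs non-forbidden negatives
    (potential false negatives) only, plus the three score histograms on a
    common binning.
    """
    p = params or DEFAULT_PARAMS
    forbidden.validate_for(matrix)
    pos_mask = matrix.positive_mask
    if not pos_mask.any():
        raise ValueError("matrix has no positive interactions")
    scores = loo_impute_all(matrix, p).scores
    pos = scores[pos_mask]
    forb = scores[forbidden.flags]
    potential = scores[~pos_mask & ~forbidden.flags]

    auc_all = auc(pos, scores[~pos_mask])
    if forb.size:
        auc_forbidden = auc(pos, forb)
    else:
        warnings.warn("empty forbidden set: positives-vs-forbidden AUC undefined")
        auc_forbidden = None
    auc_potential = auc(pos, potential) if potential.size else None

    lo, hi = float(scores.min()), float(scores.max())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_hist_bins + 1)
    hist = {
        name: np.histogram(arr, bins=edges)[0]
        for name, arr in (
            ("positive", pos),
            ("forbidden", forb),
            ("potential_fn", potential),
        )
    }
    return ExperimentReport(
        experiment="forbidden_links",
        dataset=matrix.name,
        params=_params_dict(p),
        variant="raw",
        seed=None,
        results={
            "auc_pos_vs_all_neg": float(auc_all),
            "auc_pos_vs_forbidden": None if auc_forbidden is None else float(auc_forbidden),
            "auc_pos_vs_potential_fn": None if auc_potential is None else float(auc_potential),
            "n_pos": int(pos.size),
            "n_forbidden": int(forb.size),
            "n_potential_fn": int(potential.size),
            "histogram_edges": edges,
            "histograms": hist,
        },
    )


def _bin_index(value: float, bins) -> int | None:
    """Half-open bins [a, b), last bin closed."""
    for k, (a, b) in enumerate(bins):
        if k == len(bins) - 1:
            if a <= value <= b:
                return k
        elif a <= value < b:
            return k
    return None


def catalogue_summary(reports: Sequence[ExperimentReport]) -> pd.DataFrame:
    """Mean AUC stratified by dataset density and positive-interaction count.

    Strata follow half-open bins [a, b) (last bin closed); empty strata are
    NaN.  Each report must carry ``density``, ``n_pos`` and an AUC
    (``auc`` or ``recovery_auc``) in its results.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    dens_labels = [f"[{a}, {b})" for a, b in DENSITY_BINS[:-1]] + [
        f"[{DENSITY_BINS[-1][0]}, {DENSITY_BINS[-1][1]}]"
    ]
    count_labels = [f"[{a}, {b})" for a, b in COUNT_BINS[:-1]] + [
        f"[{COUNT_BINS[-1][0]}, inf)"
    ]
    sums = np.zeros((len(DENSITY_BINS), len(COUNT_BINS)))
    counts = np.zeros_like(sums)
    for rep in reports:
        res = rep.results
        a = res.get("auc", res.get("recovery_auc"))
        if a is None or "density" not in res or "n_pos" not in res:
            raise ValueError(f"report {rep.experiment!r} lacks auc/density/n_pos")
        di = _bin_index(res["density"], DENSITY_BINS)
        ci = _bin_index(res["n_pos"], COUNT_BINS)
        if di is None or ci is None:
            continue
        sums[di, ci] += a
        counts[di, ci] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(means, index=dens_labels, columns=count_labels)
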