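"""Ranking statistics with bootstrap uncertainties.

Predicted binding free energies are compared against experimental
values with four metrics:

- offset-corrected mean unsigned error (MUE): MMPBSA totals carry a
  large systematic offset from experiment, so the mean signed error is
  removed before taking the mean absolute error;
- the Pearlman-Charifson predictive index (PI): pairwise concordance of
  predicted vs experimental ordering, weighted by the experimental
  affinity difference of each pair;
- squared Pearson correlation r^2;
- Spearman rank correlation r_s (average ranks on ties).

Uncertainties come from bootstrap resampling: N data points are
resampled with replacement, the statistic recomputed, and the standard
deviation over resamples reported as the SE.  For correlation metrics
the resampling unit is the (predicted, experimental) ligand pair; for
per-ligand free energies it is the replica average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError

DEFAULT_N_BOOT = 5000


@dataclass
class RankingReport:
    """Ranking metrics for one protocol with bootstrap SEs."""

    protocol: str
    n_ligands: int
    mue: float
    pi: float
    r2: float
    rs: float
    mue_se: float
    pi_se: float
    r2_se: float
    rs_se: float
    n_boot: int
    seed: int
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.pi <= 1.0 + 1e-12):
            raise ValueError("PI outside [-1, 1]")
        if not (0.0 - 1e-12 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 outside [0, 1]")
        if not (-1.0 - 1e-12 <= self.rs <= 1.0 + 1e-12):
            raise ValueError("rs outside [-1, 1]")
        if self.mue < 0:
            raise ValueError("MUE must be non-negative")


def bootstrap_stat(values: Sequence[float], statistic: Callable[[np.ndarray], float],
                   n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> tuple[float, float]:
    """Point estimate and bootstrap SE of a reduction over 1-D data.

    ``n_boot`` resamples of size N with replacement; the SE is the
    standard deviation of the statistic over resamples.  Fully
    reproducible for a given seed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least 2 data points")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    point = float(statistic(x))
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    boots = np.array([statistic(x[row]) for row in idx])
    return point, float(boots.std(ddof=1))


def _paired(pred, expt, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    e = np.asarray(expt, dtype=float)
    if p.shape != e.shape or p.ndim != 1:
        raise ValueError("pred and expt must be 1-D of equal length")
    if len(p) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return p, e


def mue_corrected(pred: Sequence[float], expt: Sequence[float]) -> float:
    """Mean unsigned error after removing the mean signed (systematic) error."""
    p, e = _paired(pred, expt)
    err = p - e
    return float(np.abs(err - err.mean()).mean())


def pearson_r2(pred: Sequence[float], expt: Sequence[float]) -> float:
    """Squared Pearson product-moment correlation."""
    p, e = _paired(pred, expt, min_n=3)
    if np.ptp(p) == 0 or np.ptp(e) == 0:
        raise UndefinedStatisticError("zero variance: Pearson r^2 undefined")
    r = sps.pearsonr(p, e).statistic
    return float(r * r)


def spearman_rs(pred: Sequence[float], expt: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    p, e = _paired(pred, expt, min_n=3)
    if np.ptp(p) == 0 or np.ptp(e) == 0:
        raise UndefinedStatisticError("zero variance: Spearman r_s undefined")
    return float(sps.spearmanr(p, e).statistic)


def predictive_index(pred: Sequence[float], expt: Sequence[float]) -> float:
    """Pairwise concordance weighted by experimental differences.

    Over all pairs i<j with weight w_ij = |expt_j - expt_i|, each pair
    scores +1 when predicted and experimental differences share sign,
    -1 when they oppose, 0 when the predictions tie;
    PI = sum(w*c)/sum(w).
    """
    p, e = _paired(pred, expt, min_n=2)
    i, j = np.triu_indices(len(p), k=1)
    de = e[j] - e[i]
    dp = p[j] - p[i]
    w = np.abs(de)
    if w.sum() == 0:
        raise UndefinedStatisticError("all experimental values equal: PI undefined")
    c = np.sign(de * dp)
    c[dp == 0] = 0.0
    return float((w * c).sum() / w.sum())


def ranking_report(results: Sequence[tuple[str, float]],
                   expt: Mapping[str, float],
                   n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                   protocol: str = "") -> RankingReport:
    """All four metrics with bootstrap SEs from paired ligand resampling.

    ``results`` is a list of (ligand_id, predicted dG); ``expt`` maps
    ligand_id to the experimental dG.  Ligands without an experimental
    value are dropped.  Bootstrap resamples in which a statistic is
    degenerate (e.g. zero variance) are skipped for that statistic and
    counted in ``n_degenerate``.
    """
    usable = [(lig, dg) for lig, dg in results if lig in expt]
    if len(usable) < 3:
        raise ValueError("need at least 3 ligands with experimental values")
    p = np.array([dg for _, dg in usable])
    e = np.array([expt[lig] for lig, _ in usable])

    point = {"mue": mue_corrected(p, e), "pi": predictive_index(p, e),
             "r2": pearson_r2(p, e), "rs": spearman_rs(p, e)}

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(p), size=(n_boot, len(p)))
    boots = {k: [] for k in point}
    n_degenerate = 0
    for row in idx:
        bp, be = p[row], e[row]
        degenerate = False
        for key, fn in (("mue", mue_corrected), ("pi", predictive_index),
                        ("r2", pearson_r2), ("rs", spearman_rs)):
            try:
                boots[key].append(fn(bp, be))
            except (UndefinedStatisticError, ValueError):
                degenerate = True
        if degenerate:
            n_degenerate += 1
    ses = {k: float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan")
           for k, v in boots.items()}

    return RankingReport(protocol=protocol, n_ligands=len(p),
                         mue=point["mue"], pi=point["pi"],
                         r2=point["r2"], rs=point["rs"],
                         mue_se=ses["mue"], pi_se=ses["pi"],
                         r2_se=ses["r2"], rs_se=ses["rs"],
                         n_boot=n_boot, seed=seed, n_degenerate=n_degenerate)
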