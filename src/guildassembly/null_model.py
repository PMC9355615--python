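"""Abundance-weighted beta-null deviation.

Null communities fix the regional species abundance distribution (column
sums of the observed table, normalized) and redraw each sample's individuals
multinomially at that sample's observed total. The deviation of observed
pairwise Bray-Curtis from the null distribution is reported either as a
standardized effect size (default) or as a raw difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .distances import bray_curtis
from .errors import DegenerateStatisticError, ValidationError
from .tabular_io import DistanceMatrix, OtuTable

__all__ = ["BetaDeviationResult", "null_communities", "beta_deviation",
           "mean_deviation_test"]


@dataclass(frozen=True)
class BetaDeviationResult:
    """Observed beta-diversity, its null distribution, and the deviation."""

    observed_beta: DistanceMatrix
    null_mean: DistanceMatrix
    null_sd: DistanceMatrix
    deviation: DistanceMatrix  # signed; NaN where flagged undefined
    n_null: int
    mode: str  # "ses" or "raw"
    seed: int
    flagged: tuple[tuple[str, str], ...] = ()

    @property
    def labels(self) -> tuple[str, ...]:
        return self.observed_beta.labels

    def deviation_values(self) -> np.ndarray:
        """Defined lower-triangle deviations (flagged cells dropped)."""
        vec = self.deviation.condensed()
        return vec[~np.isnan(vec)]


def null_communities(table: OtuTable, n_null: int, seed: int
                     ) -> Iterator[OtuTable]:
    """Yield ``n_null`` independent null tables.

    Regional probabilities are the observed column sums normalized; each
    null sample redraws its observed total multinomially from them.
    """
    if n_null < 1:
        raise ValidationError(f"n_null must be >= 1, got {n_null}")
    if table.n_samples == 0 or table.n_otus == 0 or table.counts.sum() == 0:
        raise ValidationError("cannot build nulls from an empty table")
    regional = table.counts.sum(axis=0).astype(float)
    probs = regional / regional.sum()
    totals = table.row_sums()
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        counts = np.vstack([rng.multinomial(int(n), probs) for n in totals])
        yield OtuTable(table.sample_ids, table.otu_ids, counts)


def beta_deviation(table: OtuTable, n_null: int = 999, mode: str = "ses",
                   seed: int = 0) -> BetaDeviationResult:
    """Compute the beta-null-deviation matrix for ``table``.

    mode="ses": (observed - null mean) / null SD elementwise;
    mode="raw": observed - null mean. Pairs whose null SD is zero in ses
    mode are flagged and set to NaN rather than silently diverging.
    """
    if mode not in ("ses", "raw"):
        raise ValidationError(f"mode must be 'ses' or 'raw', got {mode!r}")
    if table.n_samples < 2:
        raise ValidationError("beta deviation needs >= 2 samples")
    if n_null < 99:
        warnings.warn(f"n_null={n_null} is low for inference; "
                      "99+ replicates recommended", stacklevel=2)
    observed = bray_curtis(table)
    obs_vec = observed.condensed()
    m = obs_vec.size
    mean = np.zeros(m)
    m2 = np.zeros(m)
    regional = table.counts.sum(axis=0).astype(float)
    probs = regional / regional.sum()
    totals = table.row_sums()
    rng = np.random.default_rng(seed)
    for k in range(1, n_null + 1):
        counts = np.vstack([rng.multinomial(int(n), probs) for n in totals])
        bc = pdist(counts.astype(float), metric="braycurtis")
        delta = bc - mean
        mean += delta / k
        m2 += delta * (bc - mean)
    sd = np.sqrt(m2 / (n_null - 1)) if n_null > 1 else np.zeros(m)
    if mode == "ses":
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = (obs_vec - mean) / sd
        undefined = sd == 0
        dev = np.where(undefined, np.nan, dev)
    else:
        dev = obs_vec - mean
        undefined = np.zeros(m, dtype=bool)
    labels = observed.labels
    iu = np.triu_indices(len(labels), k=1)
    flagged = tuple((labels[i], labels[j])
                    for i, j, u in zip(iu[0], iu[1], undefined) if u)
    return BetaDeviationResult(
        observed_beta=observed,
        null_mean=DistanceMatrix.from_condensed(labels, mean),
        null_sd=DistanceMatrix.from_condensed(labels, sd),
        deviation=DistanceMatrix.from_condensed(labels, dev, signed=True),
        n_null=n_null, mode=mode, seed=seed, flagged=flagged)


def mean_deviation_test(result: BetaDeviationResult) -> dict:
    """One-sample two-sided t-test of the mean pairwise deviation against 0.

    Pairwise deviations are treated as observations, the convention of the
    analysis this reproduces; they are not independent, so the p-value is
    anti-conservative (noted in the output).
    """
    values = result.deviation_values()
    if values.size < 2:
        raise DegenerateStatisticError(
            "need >= 2 defined pairwise deviations for the t-test")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    n = values.size
    if sd == 0:
        if mean == 0:
            t, p = 0.0, 1.0
        else:
            raise DegenerateStatisticError(
                "all deviations identical and nonzero; t undefined")
    else:
        t = mean / (sd / math.sqrt(n))
        p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return {"mean": mean, "t": float(t), "p": p, "n_pairs": int(n),
            "note": "pairs treated as independent observations"}
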