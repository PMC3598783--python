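"""Poisson background modelling and enrichment filtering of site counts.

Site read-count distributions from resistant pools are bi-phasic: a large
family of sites at low counts (1-50 reads) arising from contaminating
non-resistant cells and stray ligation/PCR products, plus a distinct family
at high counts (100 reads upwards) marking genuine insertions in resistant
cells.  The background family is modelled as Poisson; a site is called
enriched when its count clears the smallest integer whose upper-tail
probability under the background drops below ``alpha``.

Two thresholding modes are provided because the screen convention of
"more than 100 reads" is itself usable as a fixed cut-off: ``fitted`` (a
truncated-Poisson maximum-likelihood fit of the background followed by a
tail scan) and ``fixed_threshold`` (count >= 101, i.e. strictly more than
100 reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sitecall import SITE_KEY

FIXED_THRESHOLD = 101  # "more than 100 reads"


@dataclass
class BackgroundModel:
    """Poisson background of low-count sites.

    ``mu`` is the background mean (None in fixed-threshold mode), ``alpha``
    the per-site significance level, ``bg_upper`` the count ceiling of the
    background support used for fitting.
    """

    mu: Optional[float]
    alpha: float = 0.05
    bg_upper: int = 50
    mode: str = "fitted"

    def __post_init__(self) -> None:
        if self.mode not in ("fitted", "fixed_threshold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fitted" and (self.mu is None or self.mu <= 0):
            raise ValueError("fitted mode requires mu > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _truncated_nll(mu: float, counts: np.ndarray, lo: int, hi: int) -> float:
    norm = stats.poisson.cdf(hi, mu) - stats.poisson.cdf(lo - 1, mu)
    if norm <= 0:
        return math.inf
    return -(stats.poisson.logpmf(counts, mu).sum() - len(counts) * math.log(norm))


def fit_background(
    counts: Sequence[int] | np.ndarray, bg_upper: int = 50, alpha: float = 0.05
) -> BackgroundModel:
    """Maximum-likelihood Poisson mean of counts truncated to [1, bg_upper].

    Counts above ``bg_upper`` are excluded before fitting (they belong to
    the signal component).  The likelihood is maximised by bracketed
    univariate search to |delta mu| < 1e-6.  Raises when fewer than 10
    background counts are available, pointing at fixed-threshold mode.
    """
    arr = np.asarray(counts, dtype=int)
    arr = arr[(arr >= 1) & (arr <= bg_upper)]
    if len(arr) < 10:
        raise ValueError(
            "fewer than 10 sites with counts in [1, bg_upper]; use "
            "BackgroundModel(mu=None, mode='fixed_threshold') instead"
        )
    res = optimize.minimize_scalar(
        _truncated_nll,
        bounds=(1e-9, float(2 * bg_upper)),
        args=(arr, 1, bg_upper),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return BackgroundModel(mu=float(res.x), alpha=alpha, bg_upper=bg_upper, mode="fitted")


def poisson_upper_tail(k: int, mu: float) -> float:
    """P(X >= k | mu) by direct summation of the mass function up to k-1."""
    if k <= 0:
        return 1.0
    term = math.exp(-mu)
    cdf = term
    for i in range(1, k):
        term *= mu / i
        cdf += term
    return max(0.0, 1.0 - cdf)


def select_threshold(model: BackgroundModel) -> int:
    """Smallest integer count deemed significantly enriched.

    Fitted mode: the smallest k with P(X >= k | mu) < alpha, found by
    summing the Poisson mass function upward.  Fixed mode: 101, i.e. the
    "more than 100 reads" convention.
    """
    if model.mode == "fixed_threshold":
        return FIXED_THRESHOLD
    mu, alpha = model.mu, model.alpha
    term = math.exp(-mu)
    cdf = term
    k = 1
    # tail(k) = 1 - cdf(k-1); advance until it drops below alpha
    while 1.0 - cdf >= alpha:
        term *= mu / k
        cdf += term
        k += 1
    return k


def filter_sites(
    table: pd.DataFrame, model: BackgroundModel, benjamini_hochberg: bool = False
) -> pd.DataFrame:
    """Annotate a site-count table with enrichment calls.

    Adds ``tail_probability`` (upper-tail P under the background, NaN when
    no mu is available), ``threshold_used`` and ``passed`` columns; the
    passed set is exactly {count >= threshold}.  With
    ``benjamini_hochberg=True`` an additional ``q_value`` column reports
    BH-adjusted tail probabilities for reference; the pass rule is
    unchanged (the screen convention applies no multiplicity correction).
    """
    threshold = select_threshold(model)
    out = table.copy()
    if len(out) == 0:
        for col in ("tail_probability", "threshold_used", "passed"):
            out[col] = pd.Series(dtype=float if col == "tail_probability" else object)
        return out
    if model.mu is not None:
        out["tail_probability"] = stats.poisson.sf(out["count"] - 1, model.mu)
    else:
        out["tail_probability"] = np.nan
    out["threshold_used"] = threshold
    out["passed"] = out["count"] >= threshold
    if benjamini_hochberg and model.mu is not None:
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(out["tail_probability"], method="fdr_bh")
        out["q_value"] = q
    return out


def merge_screens(
    screens: Iterable[Tuple[str, str, pd.DataFrame]]
) -> pd.DataFrame:
    """Collapse replicate screens into independent insertion events.

    ``screens`` yields ``(library_id, replicate_id, site table)`` where the
    tables carry at least the site key columns and ``count``.  A site key
    seen in several replicates of one library is one independent event
    (re-screening the same library re-samples the same clones); the same
    key in different libraries is one event per library.  Each event
    records its total reads and source replicates.
    """
    rows = []
    for library_id, replicate_id, table in screens:
        for r in table.itertuples(index=False):
            rows.append(
                (
                    library_id,
                    replicate_id,
                    r.chromosome,
                    r.csp6i_coordinate,
                    r.read_strand,
                    r.count,
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["library_id", *SITE_KEY, "total_reads", "n_replicates", "replicates"]
        )
    frame = pd.DataFrame(
        rows,
        columns=["library_id", "replicate_id", *SITE_KEY, "count"],
    )
    events = (
        frame.groupby(["library_id", *SITE_KEY], as_index=False)
        .agg(
            total_reads=("count", "sum"),
            n_replicates=("replicate_id", "nunique"),
            replicates=("replicate_id", lambda s: ";".join(sorted(set(s)))),
        )
        .sort_values(["library_id", *SITE_KEY], ignore_index=True)
    )
    return events
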