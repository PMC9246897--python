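"""Scoring of brief psychomotor vigilance test (PVT-B) reaction-time bouts.

A bout is the sequence of responses from one 3-minute test: reaction times in
milliseconds to visual stimuli, plus premature presses (false starts).  From a
bout we derive

* **lapses** — responses slower than a lapse threshold (355 ms by convention
  for the brief test);
* **false starts** — premature or anticipatory responses (below 100 ms, or
  presses with no stimulus on screen);
* **OPS** — the Overall Performance Score,
  ``1 − (false starts + lapses) / valid stimuli``, so 1 is perfect and 0 is
  the worst possible performance;
* **LRM-50** — a likelihood-ratio metric over 50 response categories
  (49 reaction-time intervals plus a false-start category).  Each response's
  category carries the ratio of its relative frequency under a sleep-deprived
  reference distribution to that under a rested one; the per-stimulus log
  ratios are summed, so 0 means the bout is equally likely under either state
  and negative values indicate rested-like (better) performance.

The canonical reference distributions come from a laboratory total
sleep-deprivation protocol and are not redistributable; this module ships a
*synthetic* default table (:func:`default_lr_table`) with the right shape and
sign behaviour, so LRM-50 values here are table-relative scores, not values
comparable to the original instrument's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RTBout",
    "LRTable",
    "BoutMetrics",
    "count_events",
    "compute_ops",
    "build_lr_table",
    "compute_lrm50",
    "standardize_lrm",
    "default_lr_table",
    "score_bout",
    "DEFAULT_LAPSE_MS",
    "DEFAULT_FALSE_START_MS",
]

logger = logging.getLogger(__name__)

#: PVT-B convention: responses at or above 355 ms are lapses,
#: responses below 100 ms are false starts.  Configurable everywhere.
DEFAULT_LAPSE_MS = 355.0
DEFAULT_FALSE_START_MS = 100.0


@dataclass(frozen=True)
class RTBout:
    """One test bout: reaction times (ms) plus stimulus bookkeeping.

    ``reaction_times`` includes premature responses (sub-threshold RTs).
    ``n_no_stimulus_presses`` counts presses with no stimulus on screen;
    these are false starts that carry no RT.  ``n_valid_stimuli`` is the
    denominator for OPS (stimuli including false starts); by default it is
    the number of recorded responses plus no-stimulus presses.
    """

    reaction_times: np.ndarray
    n_no_stimulus_presses: int = 0
    n_valid_stimuli: int | None = None

    def __post_init__(self) -> None:
        rts = np.asarray(self.reaction_times, dtype=float)
        if rts.ndim != 1:
            raise ValueError("reaction_times must be one-dimensional")
        if np.any(rts < 0):
            raise ValueError("reaction_times must be nonnegative")
        object.__setattr__(self, "reaction_times", rts)
        if self.n_no_stimulus_presses < 0:
            raise ValueError("n_no_stimulus_presses must be nonnegative")
        n_default = len(rts) + self.n_no_stimulus_presses
        if self.n_valid_stimuli is None:
            object.__setattr__(self, "n_valid_stimuli", n_default)
        elif self.n_valid_stimuli < len(rts):
            raise ValueError(
                "n_valid_stimuli is smaller than the number of recorded responses"
            )


@dataclass(frozen=True)
class LRTable:
    """Likelihood-ratio lookup over 50 response categories.

    ``bin_edges`` are 49 strictly increasing RT boundaries (ms).  Category
    ``j`` (0-based, j = 0..48) covers ``[edges[j], edges[j+1])`` with the last
    interval open-ended ``[edges[48], ∞)``; responses below ``edges[0]`` and
    no-stimulus presses fall in the false-start category, stored last.
    ``likelihood_ratios`` holds 49 interval ratios followed by the
    false-start ratio (50 values, all positive).
    """

    bin_edges: np.ndarray
    likelihood_ratios: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        ratios = np.asarray(self.likelihood_ratios, dtype=float)
        if edges.shape != (49,):
            raise ValueError("bin_edges must contain exactly 49 boundaries")
        if ratios.shape != (50,):
            raise ValueError("likelihood_ratios must contain exactly 50 values")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(ratios <= 0) or not np.all(np.isfinite(ratios)):
            raise ValueError("likelihood_ratios must be finite and positive")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "likelihood_ratios", ratios)

    @property
    def false_start_ratio(self) -> float:
        return float(self.likelihood_ratios[-1])

    def categorize(self, rts: np.ndarray) -> np.ndarray:
        """Map RTs to category indices 0..49 (49 = false start)."""
        rts = np.asarray(rts, dtype=float)
        idx = np.searchsorted(self.bin_edges, rts, side="right") - 1
        cats = np.where(idx < 0, 49, np.minimum(idx, 48))
        return cats

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "likelihood_ratios": self.likelihood_ratios.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LRTable":
        return cls(np.asarray(d["bin_edges"]), np.asarray(d["likelihood_ratios"]))


@dataclass(frozen=True)
class BoutMetrics:
    lapses: int
    false_starts: int
    ops: float
    lrm50: float
    lrm50_std: float | None = None


def count_events(
    bout: RTBout,
    lapse_threshold_ms: float = DEFAULT_LAPSE_MS,
    false_start_threshold_ms: float = DEFAULT_FALSE_START_MS,
    *,
    include_subthreshold_false_starts: bool = True,
) -> tuple[int, int]:
    """Count lapses and false starts in a bout.

    Lapses are valid responses with RT at or above the lapse threshold.
    False starts are no-stimulus presses plus (by default) responses below
    the false-start threshold; set ``include_subthreshold_false_starts=False``
    to count only no-stimulus presses.
    """
    if lapse_threshold_ms <= 0 or false_start_threshold_ms <= 0:
        raise ValueError("thresholds must be positive")
    if false_start_threshold_ms >= lapse_threshold_ms:
        raise ValueError("false-start threshold must be below the lapse threshold")
    rts = bout.reaction_times
    if len(rts) == 0 and bout.n_no_stimulus_presses == 0:
        raise ValueError("empty bout: no responses recorded")
    lapses = int(np.sum(rts >= lapse_threshold_ms))
    false_starts = bout.n_no_stimulus_presses
    if include_subthreshold_false_starts:
        false_starts += int(np.sum(rts < false_start_threshold_ms))
    return lapses, false_starts


def compute_ops(lapses: int, false_starts: int, n_valid_stimuli: int) -> float:
    """Overall Performance Score: 1 − (false starts + lapses) / valid stimuli."""
    if n_valid_stimuli < 1:
        raise ValueError("n_valid_stimuli must be at least 1")
    if lapses < 0 or false_starts < 0:
        raise ValueError("counts must be nonnegative")
    return 1.0 - (false_starts + lapses) / n_valid_stimuli


def build_lr_table(
    sdp_rts: np.ndarray,
    nonsdp_rts: np.ndarray,
    *,
    n_bins: int = 50,
    smoothing: float = 0.5,
    false_start_threshold_ms: float = DEFAULT_FALSE_START_MS,
    sdp_no_stimulus: int = 0,
    nonsdp_no_stimulus: int = 0,
) -> LRTable:
    """Build a likelihood-ratio table from sleep-deprived vs rested RT samples.

    Interval edges are quantiles of the pooled valid (non-false-start) RTs so
    every interval is populated in the pool; per category the ratio is the
    relative frequency under the sleep-deprived sample divided by that under
    the rested sample, with ``smoothing`` pseudo-counts added per category so
    ratios stay finite and positive.
    """
    sdp = np.asarray(sdp_rts, dtype=float)
    nonsdp = np.asarray(nonsdp_rts, dtype=float)
    if len(sdp) == 0 or len(nonsdp) == 0:
        raise ValueError("both RT samples must be nonempty")
    if n_bins != 50:
        raise ValueError("the metric is defined over 50 categories")
    if smoothing <= 0:
        raise ValueError("smoothing pseudo-count must be positive")

    pooled = np.concatenate([sdp, nonsdp])
    pooled_valid = pooled[pooled >= false_start_threshold_ms]
    if len(np.unique(pooled_valid)) < 49:
        raise ValueError(
            "degenerate RT samples: too few distinct values to form 49 intervals; "
            "provide a wider-spread sample or fewer bins"
        )
    # 49 intervals: edges[0] = false-start threshold, then 48 interior
    # quantile cuts; last interval is open-ended.
    qs = np.linspace(0, 1, 50)[:-1][1:]  # 48 interior quantiles
    interior = np.quantile(pooled_valid, qs)
    edges = np.concatenate([[false_start_threshold_ms], interior])
    # force strict monotonicity in the face of heavy ties
    eps = 1e-9
    for j in range(1, len(edges)):
        if edges[j] <= edges[j - 1]:
            edges[j] = edges[j - 1] + eps

    def _counts(rts: np.ndarray, no_stim: int) -> np.ndarray:
        idx = np.searchsorted(edges, rts, side="right") - 1
        cats = np.where(idx < 0, 49, np.minimum(idx, 48))
        c = np.bincount(cats, minlength=50).astype(float)
        c[49] += no_stim
        return c

    c_sdp = _counts(sdp, sdp_no_stimulus) + smoothing
    c_non = _counts(nonsdp, nonsdp_no_stimulus) + smoothing
    ratios = (c_sdp / c_sdp.sum()) / (c_non / c_non.sum())
    return LRTable(bin_edges=edges, likelihood_ratios=ratios)


def compute_lrm50(bout: RTBout, table: LRTable) -> float:
    """LRM-50 score of a bout: sum of per-stimulus log likelihood ratios.

    Computed as a sum of logs (never a raw product) for numerical stability.
    RTs below the table's support are false starts by construction; RTs above
    fall in the open-ended top interval.
    """
    cats = table.categorize(bout.reaction_times)
    log_ratios = np.log(table.likelihood_ratios)
    total = float(np.sum(log_ratios[cats]))
    total += bout.n_no_stimulus_presses * float(np.log(table.false_start_ratio))
    return total


def standardize_lrm(
    series: np.ndarray,
    stats_source: np.ndarray | None = None,
    *,
    participant: str | int | None = None,
) -> np.ndarray:
    """Standardize a participant's LRM-50 series to z-scores.

    ``stats_source`` supplies the observations whose mean/SD (sample SD,
    ddof=1) define the scaling — pass the training window to avoid test-set
    leakage inside cross-validation, or the full series to reproduce global
    scaling.  Defaults to the series itself.
    """
    x = np.asarray(series, dtype=float)
    src = x if stats_source is None else np.asarray(stats_source, dtype=float)
    if len(src) < 2:
        raise ValueError("need at least 2 observations to estimate scaling stats")
    mu = src.mean()
    sd = src.std(ddof=1)
    if sd == 0:
        who = f" for participant {participant}" if participant is not None else ""
        raise ValueError(f"zero standard deviation in scaling window{who}")
    return (x - mu) / sd


def default_lr_table(seed: int = 20220630) -> LRTable:
    """A synthetic stand-in reference table (NOT the canonical instrument).

    Built from seeded lognormal RT draws emulating a rested state (median
    ≈ 250 ms) and a sleep-deprived state (slower, heavier right tail, more
    false starts).  Deterministic given the seed.  Scores computed against
    it are internally consistent but not comparable to published values.
    """
    rng = np.random.default_rng(seed)
    n = 200_000
    rested = rng.lognormal(mean=np.log(250.0), sigma=0.18, size=n)
    deprived = rng.lognormal(mean=np.log(300.0), sigma=0.30, size=n)
    # premature presses: rare when rested, more common when deprived
    return build_lr_table(
        deprived,
        rested,
        sdp_no_stimulus=int(0.04 * n),
        nonsdp_no_stimulus=int(0.005 * n),
    )


def score_bout(
    bout: RTBout,
    table: LRTable | None = None,
    *,
    lapse_threshold_ms: float = DEFAULT_LAPSE_MS,
    false_start_threshold_ms: float = DEFAULT_FALSE_START_MS,
) -> BoutMetrics:
    """Score one bout into lapses, false starts, OPS and LRM-50."""
    if table is None:
        table = default_lr_table()
    lapses, false_starts = count_events(
        bout, lapse_threshold_ms, false_start_threshold_ms
    )
    ops = compute_ops(lapses, false_starts, bout.n_valid_stimuli)
    lrm = compute_lrm50(bout, table)
    return BoutMetrics(lapses=lapses, false_starts=false_starts, ops=ops, lrm50=lrm)
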