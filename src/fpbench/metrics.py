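"""Evaluation metrics for ranked screening results: AUC, EF, RIE, BEDROC.

Notation: n = number of actives in the test set, N = total test-set size,
r_i = 1-based rank of the i-th active.

* AUC — area under the ROC curve, the fraction of (active, inactive) pairs
  ranked correctly; 0.5 is random, 1.0 perfect.
* EF(chi) — actives found in the top fraction chi over the random
  expectation: sum_i delta(r_i <= chi*N) / (chi*n).  Bounded by 1/chi when
  chi >= n/N, else by N/n.
* RIE(alpha) — exponentially rank-weighted enrichment,
  sum_i exp(-alpha r_i / N) divided by its analytic random average
  (n/N)(1 - e^-alpha)/(e^(alpha/N) - 1); ~1 under random ranking.
* BEDROC(alpha) — RIE min-max normalised to [0, 1] using the closed-form
  bounds RIE_min/RIE_max.

All metrics depend only on the order of the list, never on the similarity
values themselves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("fpbench")


class MetricError(ValueError):
    """Undefined metric (no actives / no inactives) or invalid parameter."""


class CompletenessError(ValueError):
    """Missing repetitions in a result set."""


@dataclass(frozen=True)
class MetricSpec:
    """An evaluation method plus its parameter (chi for EF, alpha for
    RIE/BEDROC; AUC takes none)."""

    name: str  # AUC | EF | RIE | BEDROC
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.name == "AUC":
            if self.parameter is not None:
                raise MetricError("AUC takes no parameter")
        elif self.name == "EF":
            if self.parameter is None or not 0.0 < self.parameter < 1.0:
                raise MetricError(f"EF requires 0 < chi < 1, got {self.parameter}")
        elif self.name in ("RIE", "BEDROC"):
            if self.parameter is None or self.parameter <= 0.0:
                raise MetricError(f"{self.name} requires alpha > 0, got {self.parameter}")
        else:
            raise MetricError(f"unknown metric {self.name!r}")

    @property
    def label(self) -> str:
        if self.parameter is None:
            return self.name
        p = self.parameter
        return f"{self.name}({p:g})"

    def __call__(self, labels: "RankedLabels | Sequence[bool]") -> float:
        r = labels if isinstance(labels, RankedLabels) else RankedLabels(labels)
        if self.name == "AUC":
            return auc(r)
        if self.name == "EF":
            return enrichment_factor(r, self.parameter)
        if self.name == "RIE":
            return rie(r, self.parameter)
        return bedroc(r, self.parameter)


def parse_methods_config(path) -> list[MetricSpec]:
    """Read an evaluation-methods config file: one ``NAME [parameter]`` pair
    per line, e.g. ``BEDROC 20`` / ``EF 0.05`` / ``AUC``."""
    specs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                param = float(parts[1]) if len(parts) > 1 else None
                specs.append(MetricSpec(parts[0], param))
            except (MetricError, ValueError) as exc:
                raise MetricError(f"{path}:{lineno}: {exc}") from exc
    if not specs:
        raise MetricError(f"{path}: no evaluation methods")
    return specs


class RankedLabels:
    """An ordered activity-label list (index 0 = best rank)."""

    def __init__(self, labels: Iterable[bool]):
        self.labels = np.asarray(list(labels), dtype=bool)
        self.N = int(self.labels.size)
        self.active_ranks = np.flatnonzero(self.labels) + 1  # 1-based
        self.n = int(self.active_ranks.size)

    def require_mixed(self) -> None:
        if self.n == 0 or self.n == self.N:
            raise MetricError(
                f"metric undefined: n={self.n} actives of N={self.N} molecules")


def auc(r: RankedLabels) -> float:
    """ROC AUC: fraction of (active, inactive) pairs ranked correctly,
    normalised by n(N - n)."""
    r.require_mixed()
    n, N = r.n, r.N
    # ranks of actives among all molecules; pairs won = sum over actives of
    # inactives ranked below
    correct = np.sum(N - r.active_ranks) - (n * (n - 1)) / 2.0
    return float(correct) / (n * (N - n))


def enrichment_factor(r: RankedLabels, chi: float) -> float:
    """EF(chi) = (actives with rank <= chi*N) / (chi * n)."""
    if not 0.0 < chi < 1.0:
        raise MetricError(f"EF requires 0 < chi < 1, got {chi}")
    r.require_mixed()
    found = int(np.sum(r.active_ranks <= chi * r.N))
    return found / (chi * r.n)


def _rie_random_denominator(n: int, N: int, alpha: float) -> float:
    # analytic random average of sum_i exp(-alpha r_i / N)
    return (n / N) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)


def rie(r: RankedLabels, alpha: float) -> float:
    """Robust initial enhancement at exponential weight alpha."""
    if alpha <= 0.0:
        raise MetricError(f"RIE requires alpha > 0, got {alpha}")
    r.require_mixed()
    if alpha * r.n / r.N > 0.1:
        logger.warning(
            "RIE condition alpha*n/N << 1 violated (alpha=%g, n=%d, N=%d): "
            "values are hard to compare across data sets", alpha, r.n, r.N)
    s = float(np.sum(np.exp(-alpha * r.active_ranks / r.N)))
    return s / _rie_random_denominator(r.n, r.N, alpha)


def rie_bounds(n: int, N: int, alpha: float) -> tuple[float, float]:
    """Closed-form (RIE_min, RIE_max) for a composition (n, N) and weight
    alpha; RIE_min < 1 < RIE_max."""
    if not 0 < n < N:
        raise MetricError(f"need 0 < n < N, got n={n}, N={N}")
    if alpha <= 0.0:
        raise MetricError(f"alpha must be positive, got {alpha}")
    ratio = N / n
    rie_min = ratio * (1.0 - math.exp(alpha * n / N)) / (1.0 - math.exp(alpha))
    rie_max = ratio * (1.0 - math.exp(-alpha * n / N)) / (1.0 - math.exp(-alpha))
    return rie_min, rie_max


def bedroc(r: RankedLabels, alpha: float) -> float:
    """BEDROC(alpha) = (RIE - RIE_min) / (RIE_max - RIE_min), in [0, 1]."""
    value = rie(r, alpha)
    lo, hi = rie_bounds(r.n, r.N, alpha)
    # clamp float-epsilon overshoot at the extremes to the documented range
    return min(1.0, max(0.0, (value - lo) / (hi - lo)))


# ---------------------------------------------------------------------------
# Stage-2 driver: evaluate ranked lists and rank fingerprints per repetition

def evaluate(results: Iterable, methods: Sequence[MetricSpec],
             expected_repetitions: int | None = None) -> pd.DataFrame:
    """Compute every metric for every ranked list and rank the fingerprints
    within each (target, method, repetition).

    ``results`` is an iterable of RankedScreenResult (scoring module).
    Returns a tidy frame with columns target, method, fingerprint,
    repetition, value, rank — rank 1 is the best score in its repetition;
    ties get average ranks.
    """
    rows = []
    seen: dict[tuple[str, str], set[int]] = {}
    for res in results:
        labels = RankedLabels([e.is_active for e in res.entries])
        seen.setdefault((res.target_id, res.fingerprint_name), set()).add(res.repetition)
        for spec in methods:
            rows.append((res.target_id, spec.label, res.fingerprint_name,
                         res.repetition, spec(labels)))
    if not rows:
        raise CompletenessError("no ranked results supplied")
    if expected_repetitions is not None:
        for (tgt, fp), reps in seen.items():
            missing = set(range(expected_repetitions)) - reps
            if missing:
                raise CompletenessError(
                    f"target {tgt!r}, fingerprint {fp!r}: missing repetitions "
                    f"{sorted(missing)}")
    df = pd.DataFrame(rows, columns=["target", "method", "fingerprint",
                                     "repetition", "value"])
    # all four metrics are higher-is-better
    df["rank"] = (
        df.groupby(["target", "method", "repetition"])["value"]
          .transform(lambda v: rankdata(-v.to_numpy(), method="average"))
    )
    return df
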