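"""Method-agreement statistics: Bland-Altman, percentage error, t-tests.

These are the validation statistics used to compare the rebreathing FRC
against a reference lung-volume measurement. They are implemented from the
definitions (differences, n-1 sample SD, 1.96 multiplier for the 95%
limits of agreement) with p-values taken from the t distribution; the test
suite cross-checks the t-tests against scipy's reference implementations.

The percentage error PE = 1.96 * SD(differences) / mean(reference) with
the exchangeability criterion PE < 0.30: a method whose PE against an
accepted reference is below 30% can replace it clinically.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "MeasurementPair",
    "AgreementStats",
    "bland_altman",
    "average_replicates",
    "paired_t_test",
    "unpaired_t_test",
    "bland_altman_plot",
]

PE_EXCHANGEABILITY_LIMIT = 0.30
LOA_Z = 1.96


@dataclass(frozen=True)
class MeasurementPair:
    """One method-vs-reference observation (both in litres)."""

    subject_id: str
    method_value: float
    reference_value: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.method_value <= 0 or self.reference_value <= 0:
            raise ValueError("method and reference values must be positive")


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary for a set of measurement pairs."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    percentage_error: float
    exchangeable: bool


def _arrays(pairs: Sequence[MeasurementPair]) -> tuple[np.ndarray, np.ndarray]:
    m = np.array([p.method_value for p in pairs], dtype=float)
    r = np.array([p.reference_value for p in pairs], dtype=float)
    return m, r


def bland_altman(
    pairs: Sequence[MeasurementPair],
    loa_z: float = LOA_Z,
    pe_limit: float = PE_EXCHANGEABILITY_LIMIT,
    pe_denominator: str = "reference",
) -> AgreementStats:
    """Bland-Altman agreement between method and reference values.

    bias = mean(method - reference); sd_diff uses the n-1 denominator;
    limits of agreement are bias +/- ``loa_z`` * sd_diff. The percentage
    error divides ``loa_z * sd_diff`` by the mean reference value
    (``pe_denominator="all"`` switches to the mean of all measurements).
    """
    if len(pairs) < 2:
        raise ValueError("insufficient pairs: Bland-Altman needs n >= 2")
    if pe_denominator not in ("reference", "all"):
        raise ValueError("pe_denominator must be 'reference' or 'all'")
    m, r = _arrays(pairs)
    d = m - r
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    denom = float(r.mean() if pe_denominator == "reference" else np.concatenate((m, r)).mean())
    pe = loa_z * sd_diff / denom
    return AgreementStats(
        n=len(pairs),
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - loa_z * sd_diff,
        loa_high=bias + loa_z * sd_diff,
        percentage_error=pe,
        exchangeable=bool(pe < pe_limit),
    )


def average_replicates(pairs: Iterable[MeasurementPair]) -> list[MeasurementPair]:
    """Collapse repeated observations to one averaged value per subject.

    The method values of a subject's replicates are arithmetically
    averaged; the reference value (a single measurement per subject) is
    left unchanged. Subjects with one replicate pass through.
    """
    groups: "OrderedDict[str, list[MeasurementPair]]" = OrderedDict()
    for p in pairs:
        groups.setdefault(p.subject_id, []).append(p)
    out: list[MeasurementPair] = []
    for sid, members in groups.items():
        refs = {round(m.reference_value, 12) for m in members}
        if len(refs) > 1:
            raise ValueError(
                f"subject {sid!r} has inconsistent reference values: {sorted(refs)}"
            )
        out.append(
            MeasurementPair(
                subject_id=sid,
                method_value=float(np.mean([m.method_value for m in members])),
                reference_value=members[0].reference_value,
                replicate=1,
            )
        )
    return out


def _two_tailed_p(t: float, df: float) -> float:
    return float(2.0 * _stats.t.sf(abs(t), df))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Student's paired t-test; returns (t, two-tailed p).

    Degenerate conventions: identical samples give (0, 1); zero variance
    of the differences with a non-zero mean gives (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired test needs two 1-D samples of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean)) * float("inf"), 0.0
    t = mean / (sd / np.sqrt(n))
    return float(t), _two_tailed_p(t, n - 1)


def unpaired_t_test(
    x: Sequence[float],
    y: Sequence[float],
    pooled: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test, Welch by default; returns (t, two-tailed p).

    ``pooled=True`` assumes equal variances (classic Student form with
    n1 + n2 - 2 degrees of freedom); the default Welch form uses the
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise ValueError("unpaired test needs two 1-D samples with n >= 2 each")
    n1, n2 = x.size, y.size
    v1, v2 = float(x.var(ddof=1)), float(y.var(ddof=1))
    delta = float(x.mean() - y.mean())
    if v1 == 0.0 and v2 == 0.0:
        if delta == 0.0:
            return 0.0, 1.0
        return float(np.sign(delta)) * float("inf"), 0.0
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = delta / se
    return float(t), _two_tailed_p(t, df)


def bland_altman_plot(
    pairs: Sequence[MeasurementPair],
    stats: AgreementStats | None = None,
    ax=None,
    path: str | None = None,
):
    """Mean-vs-difference plot with bias and limits-of-agreement lines."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if stats is None:
        stats = bland_altman(pairs)
    m, r = _arrays(pairs)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((m + r) / 2.0, m - r, color="tab:blue", zorder=3)
    ax.axhline(stats.bias, color="k", label=f"bias {stats.bias:+.2f} L")
    for v in (stats.loa_low, stats.loa_high):
        ax.axhline(v, color="k", linestyle="--")
    ax.set_xlabel("mean of method and reference (L)")
    ax.set_ylabel("method - reference (L)")
    ax.legend(loc="best")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
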