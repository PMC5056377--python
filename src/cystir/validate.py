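"""Method-comparison statistics: Pearson correlation and Bland-Altman.

The agreement between the spectroscopic method and a clinical comparator is
summarized by the mean bias of paired differences and 95% limits of
agreement at bias +/- 1.96 * sd (n-1 standard deviation).  The difference
orientation is fixed as (comparator - FTIR), so a comparator that reads high
— as the Jaffe creatinine assay does — yields a positive bias.

For total-cystine comparisons the spectroscopic insoluble values are offset
by +1 mM (the solubility limit) when cystine was detected; undetected
samples enter as censored 0.5 mM points carrying a 0.5 mM half-width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, PairingError
from .quantify import (
    CENSORED_CENTRE_MM,
    CENSORED_HALFWIDTH_MM,
    SOLUBILITY_OFFSET_MM,
    QuantResult,
)

#: Two-sided 95% normal quantile used for the limits of agreement.
LOA_Z = 1.96


@dataclass
class MethodComparison:
    """Paired two-method comparison with Bland-Altman agreement limits.

    Differences are (method_a - method_b); the orientation is recorded so a
    positive bias is unambiguous.
    """

    pairs: list[tuple[float, float, str]]      # (method_a, method_b, sample id)
    pearson_r: float
    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    outliers: list[str]
    orientation: str = "method_a - method_b"
    halfwidths: dict[str, float] = field(default_factory=dict)

    def to_plot_data(self) -> dict:
        """Bland-Altman plot payload: points, bias line, two limit lines."""
        points = [
            {"id": sid, "mean": 0.5 * (a + b), "difference": a - b,
             "halfwidth": self.halfwidths.get(sid, 0.0)}
            for a, b, sid in self.pairs
        ]
        return {
            "kind": "bland-altman",
            "orientation": self.orientation,
            "points": points,
            "bias_line": self.mean_bias,
            "limit_lines": [self.loa_low, self.loa_high],
            "outliers": list(self.outliers),
            "pearson_r": self.pearson_r,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.to_plot_data()
        payload.update(sd_diff=self.sd_diff, n=len(self.pairs))
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def pearson_r(pairs: Sequence[tuple[float, float] | tuple[float, float, str]]
              ) -> float:
    """Product-moment correlation of paired values.

    Needs >= 3 pairs and non-zero variance in both methods.
    """
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"pearson_r needs >= 3 pairs, got {len(pairs)}")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise InsufficientDataError(
            "correlation undefined: one method has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def bland_altman(pairs: Sequence[tuple[float, float] | tuple[float, float, str]],
                 halfwidths: Mapping[str, float] | None = None,
                 ) -> MethodComparison:
    """Bland-Altman agreement analysis of paired measurements.

    Returns the mean bias of (method_a - method_b), limits of agreement at
    bias +/- 1.96 sd (n-1 denominator), and the ids of points outside the
    limits.  Pearson r is included when >= 3 pairs with variance exist, else
    reported as NaN.
    """
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"bland_altman needs >= 2 pairs, got {len(pairs)}")
    norm: list[tuple[float, float, str]] = []
    for i, p in enumerate(pairs):
        sid = str(p[2]) if len(p) > 2 else f"pair{i}"
        norm.append((float(p[0]), float(p[1]), sid))
    a = np.asarray([p[0] for p in norm])
    b = np.asarray([p[1] for p in norm])
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa_low = bias - LOA_Z * sd
    loa_high = bias + LOA_Z * sd
    outliers = [sid for d, (_, _, sid) in zip(diff, norm)
                if d < loa_low or d > loa_high]
    try:
        r = pearson_r(norm)
    except InsufficientDataError:
        r = float("nan")
    return MethodComparison(
        pairs=norm,
        pearson_r=r,
        mean_bias=bias,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        outliers=outliers,
        halfwidths=dict(halfwidths or {}),
    )


def comparison_with_offset(ftir_results: Iterable[QuantResult],
                           comparator_totals: Mapping[str, float],
                           offset: float = SOLUBILITY_OFFSET_MM,
                           include_censored: bool = True,
                           ) -> MethodComparison:
    """Compare FTIR total cystine against a total-cystine comparator.

    Detected samples enter as (insoluble + offset); undetected samples enter
    as censored 0.5 mM points with a 0.5 mM half-width (or are excluded when
    `include_censored` is False).  Differences are (comparator - FTIR).
    Unmatched ids on either side raise :class:`PairingError`.
    """
    results = list(ftir_results)
    ftir_ids = {r.sample_id for r in results}
    comp_ids = set(comparator_totals)
    unmatched = sorted(ftir_ids ^ comp_ids)
    if unmatched:
        raise PairingError(f"unmatched sample ids between methods: {unmatched}")
    pairs: list[tuple[float, float, str]] = []
    halfwidths: dict[str, float] = {}
    for r in results:
        if r.censored:
            if not include_censored:
                continue
            ftir_total = CENSORED_CENTRE_MM
            halfwidths[r.sample_id] = CENSORED_HALFWIDTH_MM
        else:
            ftir_total = r.insoluble_cystine_mM + offset
        pairs.append((float(comparator_totals[r.sample_id]), ftir_total,
                      r.sample_id))
    comparison = bland_altman(pairs, halfwidths=halfwidths)
    comparison.orientation = "comparator - ftir_total"
    return comparison


def plot_comparison(comparison: MethodComparison, path: str | Path,
                    title: str = "Method comparison") -> None:
    """Render scatter + Bland-Altman panels to an image file (png/svg)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    a = np.array([p[0] for p in comparison.pairs])
    b = np.array([p[1] for p in comparison.pairs])
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(b, a, s=18)
    lim = [0, max(1e-9, float(max(a.max(), b.max())) * 1.05)]
    ax1.plot(lim, lim, "k--", lw=0.8)
    ax1.set_xlabel("FTIR / method B")
    ax1.set_ylabel("comparator / method A")
    ax1.set_title(title)
    mean = 0.5 * (a + b)
    diff = a - b
    errs = np.array([comparison.halfwidths.get(p[2], 0.0)
                     for p in comparison.pairs])
    ax2.errorbar(mean, diff, yerr=errs, fmt="o", ms=4, lw=0.8)
    ax2.axhline(comparison.mean_bias, ls="--", color="k")
    ax2.axhline(comparison.loa_low, ls=":", color="k")
    ax2.axhline(comparison.loa_high, ls=":", color="k")
    ax2.set_xlabel("mean of methods")
    ax2.set_ylabel(comparison.orientation)
    ax2.set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
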