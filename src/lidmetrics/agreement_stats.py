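"""Method-comparison statistics: ICC with qualitative bands, Bland–Altman.

Used to validate the automated measurements against a reference technique
on paired per-subject values.  The intraclass correlation defaults to the
two-way random-effects, single-measure, absolute-agreement form (ICC(2,1)),
appropriate when two measurement systems are assessed for interchangeability
(a systematic offset between the systems lowers it); the consistency form
ICC(3,1) is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

#: qualitative agreement bands on the ICC value
ICC_BANDS = (
    (0.40, "poor"),
    (0.60, "fair"),
    (0.75, "good"),
    (np.inf, "excellent"),
)


@dataclass(frozen=True)
class AgreementReport:
    n: int
    icc: float
    icc_band: str
    mean_diff: float
    loa_low: float
    loa_high: float
    ci95_mean_diff: tuple[float, float]


def icc_band(icc: float) -> str:
    """Map an ICC value to its qualitative band (poor/fair/good/excellent)."""
    for upper, name in ICC_BANDS:
        if icc < upper:
            return name
    return "excellent"


def _paired(a, b, min_n: int):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have equal length")
    if a.size < min_n:
        raise ParameterError(f"need at least {min_n} pairs, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("paired vectors must be finite")
    return a, b


def icc_agreement(a, b, form: str = "ICC2") -> tuple[float, str]:
    """Intraclass correlation between two raters/methods, with its band.

    ``form="ICC2"`` (default) is the single-measure absolute-agreement
    two-way random-effects coefficient; ``form="ICC3"`` the consistency
    variant.  Delegates the variance decomposition to
    :func:`pingouin.intraclass_corr`.
    """
    a, b = _paired(a, b, 3)
    if np.var(np.concatenate([a, b])) == 0:
        raise ParameterError("ICC undefined: zero total variance")
    if form not in ("ICC1", "ICC2", "ICC3"):
        raise ParameterError(f"unsupported ICC form {form!r}")
    if np.array_equal(a, b):  # perfect agreement: zero error variance
        return 1.0, icc_band(1.0)
    import pingouin as pg

    data = pd.DataFrame({
        "subject": np.tile(np.arange(a.size), 2),
        "rater": np.repeat(["a", "b"], a.size),
        "score": np.concatenate([a, b]),
    })
    table = pg.intraclass_corr(data=data, targets="subject", raters="rater",
                               ratings="score")
    label = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}[form]
    icc = float(table.set_index("Type").loc[label, "ICC"])
    return icc, icc_band(icc)


def bland_altman(a, b):
    """Bland–Altman mean difference, 95% limits of agreement, and CI.

    Differences are ``d = a - b``; the limits of agreement are
    ``mean(d) +- 1.96 * SD(d)`` (n-1 denominator) and the confidence
    interval of the mean difference uses the t distribution.
    Returns ``(mean_diff, loa_low, loa_high, (ci_low, ci_high))``.
    """
    a, b = _paired(a, b, 3)
    d = a - b
    n = d.size
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = md - 1.96 * sd, md + 1.96 * sd
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return md, float(loa_low), float(loa_high), (float(md - half), float(md + half))


def agreement_report(a, b, form: str = "ICC2") -> AgreementReport:
    """Full agreement summary between two paired measurement series."""
    icc, band = icc_agreement(a, b, form=form)
    md, lo, hi, ci = bland_altman(a, b)
    return AgreementReport(
        n=int(np.asarray(a).size), icc=icc, icc_band=band,
        mean_diff=md, loa_low=lo, loa_high=hi, ci95_mean_diff=ci,
    )


def paired_compare(a, b) -> dict:
    """Both paired-difference tests (Wilcoxon signed-rank and paired t).

    Reported side by side so the caller can pick the assumption set
    appropriate to the data; no arbitration is attempted here.
    """
    a, b = _paired(a, b, 3)
    t_stat, t_p = stats.ttest_rel(a, b)
    try:
        w_stat, w_p = stats.wilcoxon(a, b)
    except ValueError:  # all differences zero
        w_stat, w_p = 0.0, 1.0
    return {
        "paired_t": {"stat": float(t_stat), "p": float(t_p)},
        "wilcoxon": {"stat": float(w_stat), "p": float(w_p)},
    }


def bland_altman_plot(a, b, path, label: str = "measurement") -> None:
    """Difference-vs-mean scatter with the mean difference and LOA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _paired(a, b, 3)
    md, lo, hi, _ = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter((a + b) / 2.0, a - b, s=12, alpha=0.6)
    for y, style in ((md, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of methods ({label})")
    ax.set_ylabel("difference (a - b)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
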