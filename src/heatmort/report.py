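"""Report emitters: results table, forest-plot data, RR-vs-AD scatter.

All emitters write plotting-ready CSV; display rounding (2 dp, half-up) is
applied only in the display columns, with unrounded values retained in the
machine columns.  The RR-vs-AD scatter carries a LOWESS smooth of RR
against log10(attributable deaths); causes whose Wald 95% CI includes 1,
or whose AD is non-positive (no logarithm), are excluded from the smooth
and listed in the drop log.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import AttributionResult, percent
from .exceptions import ValidationError
from .glm import FitResult

__all__ = ["lowess_fit", "make_report", "results_table", "file_digest"]


def lowess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 1.0, x_eval: np.ndarray | None = None
) -> pd.DataFrame:
    """Locally weighted linear scatterplot smoothing (tricube weights).

    At each evaluation point the nearest ``ceil(span * n)`` observations
    form the window; observations are weighted by
    ``(1 - (d / h)^3)^3`` with ``h`` the window radius, and a weighted
    straight line is fitted and evaluated at the point.  With span 1.0
    every window holds all points.  Returns a DataFrame with columns
    ``x`` and ``y_smooth`` sorted by x.

    This is the non-robust single-pass variant: adequate for the smooth
    trend line of an RR-vs-AD scatter, where there are few points and no
    heavy-tailed residuals to downweight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValidationError(f"LOWESS needs at least 3 points, got {n}")
    if not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    k = max(2, int(np.ceil(span * n)))
    if x_eval is None:
        x_eval = np.sort(x)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        h = np.sort(d)[k - 1]
        if h == 0:
            # all in-window points coincide with x0: plain mean
            out[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, 1.0) ** 3
        sw = w.sum()
        xw = (w * x).sum() / sw
        yw = (w * y).sum() / sw
        sxx = (w * (x - xw) ** 2).sum()
        if sxx <= 1e-12 * (np.abs(xw) + 1) ** 2:
            out[i] = yw
        else:
            slope = (w * (x - xw) * (y - yw)).sum() / sxx
            out[i] = yw + slope * (x0 - xw)
    return pd.DataFrame({"x": np.asarray(x_eval, dtype=float), "y_smooth": out})


def results_table(
    fits: list[FitResult], attrs: list[AttributionResult]
) -> pd.DataFrame:
    """Machine-readable analog of the headline results table.

    One row per cause: RR per 1 degC above threshold with Wald 95% CI,
    attributable deaths (unrounded and rounded), and AD as a percentage of
    the cause's own warm-season deaths and of all-cause warm-season deaths.
    Display columns (suffix ``_disp``) are rounded half-up.
    """
    by_cause = {a.cause: a for a in attrs}
    rows = []
    for fit in fits:
        a = by_cause.get(fit.cause)
        if a is None:
            raise ValidationError(f"no attribution result for cause {fit.cause!r}")
        rows.append(
            {
                "cause": fit.cause,
                "rr": fit.rr,
                "ci_low": fit.rr_ci_low,
                "ci_high": fit.rr_ci_high,
                "beta": fit.beta,
                "se_beta": fit.se_beta,
                "dispersion": fit.dispersion,
                "n_days": fit.n_days,
                "converged": fit.converged,
                "ad": a.attributable_deaths,
                "ad_rounded": a.ad_rounded,
                "deaths_cause_season": a.deaths_cause_season,
                "deaths_all_season": a.deaths_all_season,
                "pct_of_cause": a.pct_of_cause_raw,
                "pct_of_total": a.pct_of_total_raw,
                "rr_disp": round(fit.rr, 2),
                "pct_of_cause_disp": percent(a.attributable_deaths, a.deaths_cause_season)
                if a.deaths_cause_season
                else np.nan,
                "pct_of_total_disp": percent(a.attributable_deaths, a.deaths_all_season)
                if a.deaths_all_season
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _significant(row: pd.Series) -> bool:
    return bool(row["ci_low"] > 1.0 or row["ci_high"] < 1.0)


def make_report(
    fits: list[FitResult],
    attrs: list[AttributionResult],
    out_dir: str | Path,
    config_echo: dict | None = None,
    input_files: dict[str, str | Path] | None = None,
    span: float = 1.0,
    render_plots: bool = False,
) -> dict[str, Path]:
    """Write the results table, forest-plot data, RR-vs-AD scatter data
    (with LOWESS smooth) and a run manifest into ``out_dir``.

    Returns the mapping of artifact name to path.  Every number in the
    emitted files is recomputed from the stored unrounded values; the
    manifest records the package version, the configuration echo and
    SHA-256 digests of the input files so a report is attributable to its
    exact inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = results_table(fits, attrs)
    paths["table"] = out_dir / "results_table.csv"
    table.to_csv(paths["table"], index=False)

    forest = table[["cause", "rr", "ci_low", "ci_high", "converged"]].copy()
    paths["forest"] = out_dir / "forest.csv"
    forest.to_csv(paths["forest"], index=False)

    scatter = table[["cause", "rr", "ci_low", "ci_high", "ad"]].copy()
    scatter["significant"] = [bool(_significant(r)) for _, r in scatter.iterrows()]
    scatter["usable"] = scatter["significant"] & (scatter["ad"] > 0)
    ad = scatter["ad"].to_numpy(dtype=float)
    log_ad = np.full(len(ad), np.nan)
    log_ad[ad > 0] = np.log10(ad[ad > 0])
    scatter["log10_ad"] = log_ad
    paths["scatter"] = out_dir / "rr_vs_ad.csv"
    scatter.to_csv(paths["scatter"], index=False)

    dropped = scatter.loc[~scatter["usable"], "cause"].tolist()
    usable = scatter[scatter["usable"]]
    if len(usable) >= 3:
        smooth = lowess_fit(
            usable["rr"].to_numpy(), usable["log10_ad"].to_numpy(), span=span
        )
        paths["lowess"] = out_dir / "rr_vs_ad_lowess.csv"
        smooth.to_csv(paths["lowess"], index=False)

    manifest = {
        "package": "heatmort",
        "version": _version(),
        "config": config_echo or {},
        "inputs": {
            name: file_digest(p) for name, p in (input_files or {}).items()
        },
        "causes": list(table["cause"]),
        "excluded_from_smooth": dropped,
        "lowess_span": span,
    }
    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if render_plots:
        _render_plots(table, usable, span, out_dir, paths)
    return paths


def _version() -> str:
    from . import __version__

    return __version__


def _render_plots(table, usable, span, out_dir: Path, paths: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1))
    ypos = np.arange(len(table))[::-1]
    ax.errorbar(
        table["rr"], ypos,
        xerr=[table["rr"] - table["ci_low"], table["ci_high"] - table["rr"]],
        fmt="o", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(ypos, table["cause"])
    ax.set_xlabel("RR per 1 degC above threshold (95% CI)")
    fig.tight_layout()
    paths["forest_png"] = out_dir / "forest.png"
    fig.savefig(paths["forest_png"], dpi=120)
    plt.close(fig)

    if len(usable) >= 3:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(usable["log10_ad"], usable["rr"])
        smooth = lowess_fit(
            usable["rr"].to_numpy(), usable["log10_ad"].to_numpy(), span=span
        )
        # smooth maps rr -> log10 AD; draw in scatter orientation
        ax.plot(smooth["y_smooth"], smooth["x"], color="C1")
        ax.set_xlabel("log10 attributable deaths")
        ax.set_ylabel("RR per 1 degC above threshold")
        fig.tight_layout()
        paths["scatter_png"] = out_dir / "rr_vs_ad.png"
        fig.savefig(paths["scatter_png"], dpi=120)
        plt.close(fig)
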