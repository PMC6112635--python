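"""Forest plot of association results."""

from __future__ import annotations

import pandas as pd


def forest_plot(results: pd.DataFrame, path: str) -> None:
    """Save a forest plot (OR with 95% CI per fitted comparison).

    Expects a ``results.csv``-style frame with ``or``, ``ci_low``,
    ``ci_high``, ``model``, ``stratum`` and ``stage`` columns; rows that
    failed to converge are drawn as unfilled markers without intervals.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results[results["stage"].isin(["primary", "stratified", "sensitivity"])].copy()
    if df.empty:
        raise ValueError("forest_plot: no validation-phase rows to draw")
    labels = [
        (row["stratum"] or row["model"].split("|")[-1].strip()) for _, row in df.iterrows()
    ]
    y = range(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    for yi, (_, row) in zip(y, df.iterrows()):
        if row.get("converged", True) and pd.notna(row["or"]):
            ax.plot([row["ci_low"], row["ci_high"]], [yi, yi], color="0.3", lw=1.4)
            ax.plot(row["or"], yi, "s", color="0.1", ms=5)
        else:
            ax.plot(1.0, yi, "o", mfc="none", mec="0.5", ms=5)
    ax.axvline(1.0, color="0.7", ls="--", lw=1)
    ax.set_yticks(list(y))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
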