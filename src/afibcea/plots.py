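"""Matplotlib figures: tornado diagram, CE-plane scatter, CEAC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_tornado(tornado: pd.DataFrame, path: str | Path, top: int = 15) -> None:
    """Horizontal bars of ICER at each parameter's range ends, widest first."""
    df = tornado.head(top).iloc[::-1]
    base = tornado.attrs.get("base_icer")
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
    for i, row in enumerate(df.itertuples()):
        lo, hi = sorted((row.icer_low, row.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.set_yticks(range(len(df)), df["parameter"])
    if base is not None:
        ax.axvline(base, color="k", lw=1, ls="--", label="base-case ICER")
        ax.legend()
    ax.set_xlabel("ICER (US $ / QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(replicates: pd.DataFrame, path: str | Path, wtp: float = 32000.0) -> None:
    """Incremental cost vs incremental effect scatter with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(replicates["delta_effect"], replicates["delta_cost"], s=4, alpha=0.25)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    xs = replicates["delta_effect"]
    grid = [xs.min(), xs.max()]
    ax.plot(grid, [wtp * x for x in grid], "r--", lw=1, label=f"WTP {wtp:,.0f} $/QALY")
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (US $)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac: dict[float, float], path: str | Path) -> None:
    """Probability cost-effective as a function of willingness to pay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    wtps = sorted(ceac)
    ax.plot(wtps, [ceac[w] for w in wtps])
    ax.set_xlabel("willingness to pay (US $ / QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
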