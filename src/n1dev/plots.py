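"""Minimal figures: GFP trace with the N1 window and TANOVA significance bar."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_gfp_tanova(gfp_df, tanova_df, window, path) -> None:
    """GFP over time, shaded N1 window, and per-sample TANOVA p-values."""
    fig, (ax, axp) = plt.subplots(
        2, 1, figsize=(7, 4), sharex=False, height_ratios=[3, 1], constrained_layout=True
    )
    ax.plot(gfp_df["time_ms"], gfp_df["gfp_uv"], color="k", lw=1.2)
    ax.axvspan(window.start_ms, window.end_ms, color="gold", alpha=0.3,
               label=f"N1 {window.start_ms:g}-{window.end_ms:g} ms")
    ax.set_ylabel("GFP (μV)")
    ax.set_xlabel("time (ms)")
    ax.legend(frameon=False, fontsize=8)
    if len(tanova_df):
        sig = tanova_df["p"] < 0.05
        axp.bar(tanova_df["sample_ms"], sig.astype(float),
                width=2.0, color="darkorange")
        axp.set_ylim(0, 1.2)
    axp.set_ylabel("p < .05")
    axp.set_xlabel("time (ms)")
    fig.savefig(path, dpi=110)
    plt.close(fig)
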