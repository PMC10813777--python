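"""Best-effort figures from a pipeline report bundle.

Produces the three standard views: the neutral-model occurrence/abundance
scatter with its fitted curve and 95% band (above = orange, neutral = gray,
below = green), the AVD bar chart with significance letters, and a PCoA
scatter colored by group. Figures are skipped when their stage output is
absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_PARTITION_COLORS = {"above": "tab:orange", "neutral": "0.6", "below": "tab:green"}


def make_figures(out_dir) -> list:
    """Render figures for whichever stages the bundle contains.

    Returns the list of written file paths.
    """
    out_dir = Path(out_dir)
    report = json.loads((out_dir / "report.json").read_text())
    written = []

    for per_zotu in sorted(out_dir.glob("ncm_per_zotu_*.tsv")):
        label = per_zotu.stem.replace("ncm_per_zotu_", "")
        df = pd.read_csv(per_zotu, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4))
        present = [p for p in ("above", "neutral", "below")
                   if (df["partition"] == p).any()]
        for part in present:
            sub = df[df["partition"] == part]
            ax.scatter(np.log10(sub["p"]), sub["f_obs"], s=8,
                       color=_PARTITION_COLORS[part], label=part, alpha=0.7)
        order = np.argsort(df["p"].to_numpy())
        logp = np.log10(df["p"].to_numpy()[order])
        ax.plot(logp, df["f_pred"].to_numpy()[order], "b-", lw=1.2)
        ax.plot(logp, df["f_lower"].to_numpy()[order], "b--", lw=0.8)
        ax.plot(logp, df["f_upper"].to_numpy()[order], "b--", lw=0.8)
        fit = report.get("ncm", {}).get(label, {})
        ax.set_title(f"{label}: Nm={fit.get('Nm', float('nan')):.0f}, "
                     f"R²={fit.get('r_squared', float('nan')):.3f}")
        ax.set_xlabel("log10 mean relative abundance")
        ax.set_ylabel("occurrence frequency")
        ax.legend(frameon=False, fontsize=8)
        path = out_dir / f"fig_ncm_{label}.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    avd_rep = report.get("avd")
    if avd_rep:
        strata = avd_rep["strata"]
        labels = [s["stratum"] for s in strata]
        values = [s["avd"] for s in strata]
        letters = avd_rep.get("letters", {})
        fig, ax = plt.subplots(figsize=(6, 4))
        bars = ax.bar(labels, values, color="tab:blue", alpha=0.8)
        for bar, lab in zip(bars, labels):
            ax.text(bar.get_x() + bar.get_width() / 2, bar.get_height(),
                    letters.get(lab, ""), ha="center", va="bottom")
        ax.set_ylabel("AVD (lower = more stable)")
        ax.tick_params(axis="x", rotation=45)
        path = out_dir / "fig_avd.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    mv_rep = report.get("multivariate")
    if mv_rep and (out_dir / "pcoa.tsv").exists():
        coords = pd.read_csv(out_dir / "pcoa.tsv", sep="\t", index_col=0)
        meta = pd.read_csv(out_dir / "metadata.tsv", sep="\t",
                           index_col=0) if (out_dir / "metadata.tsv").exists() else None
        fig, ax = plt.subplots(figsize=(5, 4))
        if meta is not None and "group" in meta.columns:
            for g, sub in coords.groupby(meta.loc[coords.index, "group"]):
                ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=12, label=str(g))
            ax.legend(frameon=False, fontsize=8, title="group")
        else:
            ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=12)
        props = mv_rep["pcoa"]["proportion_explained"]
        ax.set_xlabel(f"PCo1 ({100 * props[0]:.1f}%)")
        if len(props) > 1:
            ax.set_ylabel(f"PCo2 ({100 * props[1]:.1f}%)")
        path = out_dir / "fig_pcoa.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    return written
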