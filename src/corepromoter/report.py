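"""Writers for fit reports, scan tables and diagnostic plots.

Every plotted quantity is also emitted as TSV so downstream checks can
read numbers instead of pixels.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .strength_model import LinearFit, ScanRow


def write_fit_report(
    fit: LinearFit,
    outdir: str | Path,
    prefix: str = "fit",
    pairs: list[tuple[str, float, float]] | None = None,
    plots: bool = False,
) -> None:
    """Write ``<prefix>.json`` (all fit fields), ``<prefix>_residuals.tsv``
    and ``<prefix>_qq.tsv``; with ``plots`` also the scatter/residual/QQ
    figures as PNG.  ``pairs`` is the (id, score, strength) data behind
    the fit and is required for the scatter plot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{prefix}.json", "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")
    pd.DataFrame(fit.residuals, columns=["id", "residual"]).to_csv(
        outdir / f"{prefix}_residuals.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        fit.qq, columns=["theoretical_quantile", "ordered_residual"]
    ).to_csv(outdir / f"{prefix}_qq.tsv", sep="\t", index=False)
    if pairs is not None:
        pd.DataFrame(pairs, columns=["id", "score", "strength"]).to_csv(
            outdir / f"{prefix}_points.tsv", sep="\t", index=False
        )
    if plots:
        _plot_fit(fit, outdir, prefix, pairs)


def _plot_fit(
    fit: LinearFit,
    outdir: Path,
    prefix: str,
    pairs: list[tuple[str, float, float]] | None,
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    if pairs is not None:
        xs = [p[1] for p in pairs]
        ys = [p[2] for p in pairs]
        axes[0].scatter(xs, ys, s=18)
        lo, hi = min(xs), max(xs)
        axes[0].plot([lo, hi], [fit.C0 + fit.C1 * lo, fit.C0 + fit.C1 * hi],
                     color="crimson")
    axes[0].set_xlabel("normalized promoter score")
    axes[0].set_ylabel("normalized promoter strength")
    axes[0].set_title(f"fit: C0={fit.C0:.3g}, C1={fit.C1:.3g}, R²={fit.r2:.3f}")
    if pairs is not None:
        resid_map = dict(fit.residuals)
        axes[1].scatter([p[1] for p in pairs],
                        [resid_map[p[0]] for p in pairs], s=18)
    axes[1].axhline(0.0, color="gray", lw=1)
    axes[1].set_xlabel("normalized promoter score")
    axes[1].set_ylabel("residual")
    axes[1].set_title("residuals")
    axes[2].scatter([q[0] for q in fit.qq], [q[1] for q in fit.qq], s=18)
    axes[2].set_xlabel("theoretical normal quantile")
    axes[2].set_ylabel("ordered residual")
    axes[2].set_title("QQ")
    fig.tight_layout()
    fig.savefig(outdir / f"{prefix}_diagnostics.png", dpi=120)
    plt.close(fig)


def scan_frame(rows: list[ScanRow]) -> pd.DataFrame:
    """Scan rows as a DataFrame: X, C0, C1, r2, adj_r2, F, p_F, error."""
    data = []
    for row in rows:
        if row.fit is None:
            data.append({"X": row.X, "error": row.error})
        else:
            f = row.fit
            data.append({
                "X": row.X, "C0": f.C0, "C1": f.C1, "r2": f.r2,
                "adj_r2": f.adj_r2, "F": f.F, "p_F": f.p_F, "error": None,
            })
    return pd.DataFrame(data)


def write_scan_table(
    rows: list[ScanRow], path: str | Path, plots: bool = False
) -> None:
    path = Path(path)
    df = scan_frame(rows)
    df.to_csv(path, sep="\t", index=False)
    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ok = df[df["error"].isna()]
        fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharex=True)
        for ax, col in zip(axes, ("r2", "adj_r2", "p_F")):
            ax.plot(ok["X"], ok[col], marker="o", ms=3)
            ax.set_xlabel("segment endpoint X")
            ax.set_ylabel(col)
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
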