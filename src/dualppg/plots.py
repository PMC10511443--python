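"""Agreement figures: estimate-vs-reference scatter and Bland–Altman plot."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluate import EvaluationReport


def agreement_plots(report: EvaluationReport, out_dir: str | Path) -> list[Path]:
    """Write scatter and Bland–Altman PNGs for one evaluation report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.errors is None:
        raise ValueError("report carries no raw errors; re-run the experiment")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    errors = np.asarray(report.errors)
    ba = report.bland_altman
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(errors, bins=40, color="steelblue", alpha=0.8)
    ax.set_xlabel(f"{report.target} error (mmHg)")
    ax.set_ylabel("windows")
    ax.set_title(f"{report.target}: ME {report.stats.me:.2f}, SD {report.stats.sd:.2f} mmHg")
    p = out / f"{report.target.lower()}_error_hist.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(errors.size)
    ax.scatter(x, errors, s=4, alpha=0.4, color="steelblue")
    for yv, style in ((ba.mu, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(yv, linestyle=style, color="crimson", linewidth=1)
    ax.set_xlabel("window")
    ax.set_ylabel(f"{report.target} estimate − reference (mmHg)")
    ax.set_title(f"LOA [{ba.loa_lower:.2f}, {ba.loa_upper:.2f}] mmHg")
    p = out / f"{report.target.lower()}_bland_altman.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
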