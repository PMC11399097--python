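"""Diagnostic report: figures mirroring the standard global-fit checks."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

log = logging.getLogger(__name__)

__all__ = ["make_report"]


def make_report(bundle: dict, outdir: str | Path | None = None) -> dict:
    """Write diagnostic figures for the available stages of a run bundle.

    Produces (when the inputs exist): time-slice overlays of data versus the
    refined kinetics, concentration curves, basis spectra, and the R^2 versus
    delta-Rg candidate scatter.  Missing stages are listed but do not prevent
    the report for the stages that are present; an empty bundle is an error.
    """
    out = Path(outdir if outdir is not None else bundle.get("outdir", "."))
    out.mkdir(parents=True, exist_ok=True)
    written, missing = [], []

    ds = bundle.get("difference")
    best = bundle.get("kinetic_best")
    if ds is not None and best is not None:
        recon = best.reconstruct()
        slices = np.unique(np.linspace(0, len(ds.time_us) - 1, 5).astype(int))
        fig, ax = plt.subplots(figsize=(6, 4))
        for j in slices:
            (line,) = ax.plot(ds.q.values, ds.delta_S[:, j], lw=0.8, alpha=0.6,
                              label=f"t = {ds.time_us[j]:.1f} us")
            ax.plot(ds.q.values, recon[:, j], color=line.get_color(), ls="--", lw=1.2)
        ax.set_xlabel("q (1/A)")
        ax.set_ylabel("dS")
        ax.legend(fontsize=7)
        ax.set_title("time slices: data (solid) vs refined kinetics (dashed)")
        fig.tight_layout()
        fig.savefig(out / "timeslices.png", dpi=120)
        plt.close(fig)
        written.append("timeslices.png")
    else:
        missing.append("timeslices (needs difference + kinetic fit)")

    if best is not None and ds is not None:
        labels = "ABC"[: best.model.n_states]
        fig, ax = plt.subplots(figsize=(6, 4))
        for i, lab in enumerate(labels):
            ax.plot(ds.time_us, best.concentrations[:, i], label=f"C_{lab}")
        ax.set_xlabel("t (us)")
        ax.set_ylabel("concentration")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "concentrations.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 4))
        for i, lab in enumerate(labels):
            ax.plot(ds.q.values, best.basis_spectra[i], label=f"BS_{lab}")
        ax.set_xlabel("q (1/A)")
        ax.set_ylabel("basis spectrum")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "spectra.png", dpi=120)
        plt.close(fig)
        written += ["concentrations.png", "spectra.png"]
    else:
        missing.append("concentrations/spectra (needs kinetic fit)")

    screen = bundle.get("screen")
    if screen is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        drg = [f.delta_rg for f in screen.fits_]
        r2 = [f.r2 for f in screen.fits_]
        sel = [f.selected for f in screen.fits_]
        ax.scatter(drg, r2, c=["tab:blue" if s else "0.6" for s in sel])
        ax.set_xlabel("delta Rg (A)")
        ax.set_ylabel("R^2")
        ax.set_title("candidate fits (blue = selected)")
        fig.tight_layout()
        fig.savefig(out / "candidates.png", dpi=120)
        plt.close(fig)
        written.append("candidates.png")
    else:
        missing.append("candidates (needs structural screen)")

    if not written:
        raise ValueError("empty bundle: no stage outputs to report on")
    summary = [f"report written to {out}", f"figures: {', '.join(written)}"]
    if missing:
        summary.append("missing stages: " + "; ".join(missing))
    (out / "report.txt").write_text("\n".join(summary) + "\n")
    return {"figures": written, "missing": missing, "outdir": str(out)}
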