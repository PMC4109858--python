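"""End-to-end pipeline: trim -> IGS extraction -> binning -> constraint
estimation -> divergence, with a JSON/TSV report and diagnostic plots.

Every report embeds the fully-serialized configuration and its hash, so a
rerun with identical inputs and configuration is byte-identical (all
randomness flows from the seed)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import alignio, nim, trim as trim_mod
from .divergence import ar_sites, hky85_distance

__all__ = ["RunConfig", "run_pipeline", "plot_igs_fit", "plot_turnover_fit", "plot_report"]


@dataclass
class RunConfig:
    maf: str
    outdir: str
    format: str = "maf"
    trim: bool = True
    methods: tuple = ("nim1",)
    n_bins: int = 20
    subset_bed: str | None = None
    buffer: int = 50
    repeats_bed: str | None = None
    n_boot: int = 1000
    seed: int = 0
    drop_unplaced: bool = True
    pseudocount: float = 1.0

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so the same analysis hashes identically anywhere)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to
    ``outdir/report.json`` with per-bin TSVs alongside)."""
    maf = Path(cfg.maf)
    if not maf.exists():
        raise FileNotFoundError(f"input alignment not found: {maf}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    blocks = list(
        alignio.read_pairwise_alignment(maf, cfg.format, drop_unplaced=cfg.drop_unplaced)
    )
    if not blocks:
        raise ValueError(f"stage read: no usable blocks in {maf}")

    if cfg.trim:
        try:
            blocks = trim_mod.trim_blocks(blocks, pseudocount=cfg.pseudocount)
        except ValueError as exc:
            raise ValueError(f"stage trim: {exc}") from exc

    records = []
    for b in blocks:
        records.extend(alignio.extract_igs(b))
    try:
        histograms = alignio.assign_gc_bins(records, cfg.n_bins)
    except ValueError as exc:
        raise ValueError(f"stage bin: {exc}") from exc
    alignio.write_histograms_tsv(histograms, outdir / "histograms.tsv")

    report: dict = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_blocks": len(blocks),
        "n_igs": len(records),
        "estimates": {},
    }

    model = nim.NeutralIndelModel(histograms)
    for method in cfg.methods:
        try:
            res = model.fit(method=method, n_boot=cfg.n_boot, seed=cfg.seed)
        except ValueError as exc:
            raise ValueError(f"stage alpha[{method}]: {exc}") from exc
        report["estimates"][method] = _estimate_dict(res.estimate)

    if cfg.subset_bed:
        subset = alignio.read_bed(cfg.subset_bed)
        est = nim.alpha_subset(
            blocks, subset, buffer=cfg.buffer, method=cfg.methods[0],
            n_bins=cfg.n_bins, n_boot=cfg.n_boot, rng=cfg.seed,
        )
        report["estimates"]["subset"] = _estimate_dict(est)

    if cfg.repeats_bed:
        repeats = alignio.read_bed(cfg.repeats_bed)
        try:
            div = hky85_distance(ar_sites(blocks, repeats))
        except ValueError as exc:
            raise ValueError(f"stage divergence: {exc}") from exc
        report["divergence"] = {
            "d": div.d, "kappa": div.kappa, "n_sites": div.n_sites,
            "base_freqs": list(div.base_freqs), "source": div.source,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str, sort_keys=True)
    _write_per_bin_tsv(report, outdir / "per_bin.tsv")
    return report


def _estimate_dict(est: nim.ConstraintEstimate) -> dict:
    out = {
        "alpha_bp": est.alpha_bp,
        "alpha_fraction": est.alpha_fraction,
        "ci95_bp": list(est.ci95),
        "method": est.method,
        "bins": list(est.bins),
    }
    per_bin = est.diagnostics.get("per_bin")
    if per_bin:
        rows = []
        for b in per_bin:
            row = {"bin": b.bins[0], "alpha_bp": b.alpha_bp, "ci95_bp": list(b.ci95)}
            fit = b.diagnostics.get("fit")
            if fit is not None:
                row.update(
                    theta=fit.theta, K=fit.K, T=fit.T,
                    log_intercept=fit.log_intercept,
                    fit_range=list(fit.fit_range), rsquared=fit.rsquared,
                )
            else:
                row.update({k: b.diagnostics.get(k) for k in ("theta", "pi", "mu_c")})
            rows.append(row)
        out["per_bin"] = rows
    if est.diagnostics.get("skipped"):
        out["skipped_bins"] = est.diagnostics["skipped"]
    return out


def _write_per_bin_tsv(report: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("method\tbin\talpha_bp\tci_low\tci_high\ttheta\tK\tT\n")
        for method, est in report["estimates"].items():
            for row in est.get("per_bin", []):
                fh.write(
                    f"{method}\t{row['bin']}\t{row['alpha_bp']:.3f}\t"
                    f"{row['ci95_bp'][0]:.3f}\t{row['ci95_bp'][1]:.3f}\t"
                    f"{row.get('theta', float('nan')):.6g}\t"
                    f"{row.get('K', float('nan')):.6g}\t{row.get('T', '')}\n"
                )


# ---------------------------------------------------------------------------
# plotting


def plot_igs_fit(hist, fit, ax=None, shade_excess: bool = True):
    """Log-scale IGS histogram with the fitted neutral line; the region
    above the threshold T (where excess is summed) is shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    xs, cs = hist.lengths_counts()
    ax.semilogy(xs, cs, ".", ms=3, color="steelblue", label="observed IGS")
    if fit is not None:
        grid = np.arange(max(xs.min(), 1), xs.max() + 1)
        ax.semilogy(grid, fit.expected(grid), "-", color="firebrick",
                    label=f"neutral fit (theta={fit.theta:.4f})")
        ax.axvspan(*fit.fit_range, color="0.9", label="fit range")
        if shade_excess:
            ax.axvspan(fit.T, xs.max(), color="goldenrod", alpha=0.2,
                       label="excess region")
    ax.set_xlabel("inter-gap segment length (bp)")
    ax.set_ylabel("count")
    ax.set_title(f"bin {hist.bin_label}")
    ax.legend(fontsize=8)
    return ax


def plot_turnover_fit(results, ax=None):
    """Constrained amount vs divergence with the fitted exponential decay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    obs = results.model.observations
    d = np.array([o.d for o in obs])
    amount = np.array([o.amount for o in obs])
    yerr = None
    if all(o.ci is not None for o in obs):
        lo = amount - np.array([o.ci[0] for o in obs])
        hi = np.array([o.ci[1] for o in obs]) - amount
        yerr = np.vstack([lo, hi])
    ax.errorbar(d, amount, yerr=yerr, fmt="o", color="steelblue", label="observed")
    grid = np.linspace(0, d.max() * 1.05, 200)
    ax.plot(grid, results.a * np.exp(-results.b * grid), "-", color="firebrick",
            label=f"a·e^(−b·d), b={results.b:.3g}")
    ax.set_xlabel("divergence d (subst./site)")
    ax.set_ylabel("constrained amount")
    ax.legend(fontsize=8)
    return ax


def plot_report(outdir: str | Path, max_bins: int = 4) -> list:
    """Regenerate diagnostic figures from a pipeline output directory."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from collections import Counter

    outdir = Path(outdir)
    with open(outdir / "report.json") as fh:
        report = json.load(fh)
    # rebuild per-bin histograms from the TSV
    hists: dict[str, Counter] = {}
    with open(outdir / "histograms.tsv") as fh:
        next(fh)
        for line in fh:
            label, length, count = line.split("\t")
            hists.setdefault(label, Counter())[int(length)] = int(count)
    figs = []
    for method, est in report["estimates"].items():
        for row in est.get("per_bin", [])[:max_bins]:
            if "theta" not in row or row.get("theta") is None or "fit_range" not in row:
                continue
            label = str(row["bin"])
            hist = alignio.IGSHistogram(bin_label=label, counts=hists.get(label, Counter()))
            fit = nim.GeometricFit(
                theta=row["theta"], log_intercept=row["log_intercept"],
                fit_range=tuple(row["fit_range"]), T=int(row["T"]),
                K=row["K"], covariance=np.zeros((2, 2)),
            )
            ax = plot_igs_fit(hist, fit)
            fig = ax.figure
            fig.savefig(outdir / f"igs_{method}_bin{label}.png", dpi=120)
            figs.append(fig)
            plt.close(fig)
    return figs
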