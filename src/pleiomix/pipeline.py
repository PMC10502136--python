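"""End-to-end orchestration: harmonize -> mixture fit -> cond/conjFDR -> loci
-> LDSC -> local correlations, driven by a single YAML config with recorded
seeds and a JSON manifest of every artifact."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fdr as _fdr
from . import ldsc as _ldsc
from . import localrg as _localrg
from . import loci as _loci
from . import mixture as _mixture
from . import simulate as _simulate
from .sumstats import (ExclusionRegions, SumStats, apply_exclusions,
                       harmonize_pair, read_panel, read_sumstats, subset_panel)

logger = logging.getLogger("pleiomix")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; see module docstrings for the science."""

    out_dir: str = "pleiomix_run"
    sumstats_1: str | None = None
    sumstats_2: str | None = None
    ld_panel: str | None = None
    exclusion_regions: str | None = None   # BED-like file; defaults used if None
    known_loci: str | None = None
    simulate: dict | None = None           # MixtureTruth fields; replaces file inputs
    cond_fdr_threshold: float = 0.01
    conj_fdr_threshold: float = 0.05
    candidate_fdr: float = 0.1
    prune_r2: float = 0.1
    n_prune: int = 100
    merge_dist: int = 250_000
    seed: int = 0
    mixture: dict = field(default_factory=dict)   # GridConfig overrides
    run_mixture: bool = True
    run_local: bool = True
    n_perm_local: int = 10_000

    def __post_init__(self) -> None:
        for name in ("cond_fdr_threshold", "conj_fdr_threshold", "candidate_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        truth = _simulate.MixtureTruth(**{**config.simulate, "seed": config.seed})
        t1, t2, _, panel = _simulate.simulate_pair(truth)
        return t1, t2, panel
    for name in ("sumstats_1", "sumstats_2", "ld_panel"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"config.{name} missing or not found: {p}")
    panel = read_panel(config.ld_panel)
    s1 = read_sumstats(config.sumstats_1)
    s2 = read_sumstats(config.sumstats_2)
    t1, t2 = harmonize_pair(s1, s2, panel)
    panel = subset_panel(panel, t1.df["SNP"])
    return t1, t2, panel


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Failures abort with the stage name; artifacts written before the failure
    are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_digest": config.digest(), "seed": config.seed, "artifacts": []}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["artifacts"].append(name)

    stage = "load"
    try:
        t1, t2, panel = _load_inputs(config)
        regions = (ExclusionRegions.from_file(config.exclusion_regions)
                   if config.exclusion_regions else ExclusionRegions())
        fit_mask = apply_exclusions(t1, regions)
        emit("trait1.sumstats.tsv", lambda p: t1.df.to_csv(p, sep="\t", index=False,
                                                           float_format="%.6g"))
        emit("trait2.sumstats.tsv", lambda p: t2.df.to_csv(p, sep="\t", index=False,
                                                           float_format="%.6g"))

        stage = "mixture"
        report = {}
        if config.run_mixture:
            cfg = _mixture.GridConfig(**config.mixture)
            ws = _mixture.MixtureWorkspace(t1.z, t2.z, panel, t1.n_eff, t2.n_eff,
                                           config=cfg)
            uni1 = _mixture.fit_univariate(t1, panel, cfg, workspace=ws, trait=1)
            uni2 = _mixture.fit_univariate(t2, panel, cfg, workspace=ws, trait=2)
            biv = _mixture.fit_bivariate(t1, t2, panel, uni1, uni2, cfg, workspace=ws)
            venn = _mixture.venn_summary(biv)
            aic = _mixture.aic_comparison(biv, t1, t2, panel, cfg, workspace=ws)
            profile = _mixture.likelihood_profile(biv, t1, t2, panel, n_grid=7,
                                                  config=cfg, workspace=ws)
            report = _mixture.fit_report(biv, venn, aic, profile)
            emit("mixture_fit.json", lambda p: Path(p).write_text(
                json.dumps(report, indent=1, default=float)))
            emit("venn_summary.tsv", venn.to_tsv)

        stage = "conditional-qq"
        qq12 = _fdr.conditional_qq(t1.p, t2.p)
        qq21 = _fdr.conditional_qq(t2.p, t1.p)

        def qq_frame(qq):
            rows = []
            for thr in qq.thresholds:
                e, o = qq.curve(thr)
                rows.append(pd.DataFrame({"threshold": thr, "expected": e,
                                          "observed": o}))
            return pd.concat(rows, ignore_index=True)

        emit("qq_trait1_given_trait2.tsv",
             lambda p: qq_frame(qq12).to_csv(p, sep="\t", index=False,
                                             float_format="%.6g"))
        emit("qq_trait2_given_trait1.tsv",
             lambda p: qq_frame(qq21).to_csv(p, sep="\t", index=False,
                                             float_format="%.6g"))

        stage = "condfdr"
        tab12 = _fdr.condfdr_table(t1.p, t2.p, fit_mask, panel,
                                   n_prune=config.n_prune, seed=config.seed,
                                   prune_r2=config.prune_r2)
        tab21 = _fdr.condfdr_table(t2.p, t1.p, fit_mask, panel,
                                   n_prune=config.n_prune, seed=config.seed + 1,
                                   prune_r2=config.prune_r2)
        cond12 = _fdr.assign_condfdr(t1.p, t2.p, tab12)
        cond21 = _fdr.assign_condfdr(t2.p, t1.p, tab21)
        conj = _fdr.conjfdr(cond12, cond21)
        per_variant = panel.index[["SNP", "CHR", "BP"]].copy()
        per_variant["P1"] = t1.p
        per_variant["P2"] = t2.p
        per_variant["condFDR_1_given_2"] = cond12
        per_variant["condFDR_2_given_1"] = cond21
        per_variant["conjFDR"] = conj
        per_variant["neglog10_conjFDR"] = -np.log10(np.clip(conj, 1e-300, None))
        emit("fdr_per_variant.tsv",
             lambda p: per_variant.to_csv(p, sep="\t", index=False,
                                          float_format="%.6g"))

        stage = "loci"
        locus_set = _loci.define_loci(conj, panel, t1.z, t2.z, t1.p, t2.p,
                                      threshold=config.conj_fdr_threshold,
                                      candidate_fdr=config.candidate_fdr,
                                      merge_dist=config.merge_dist)
        _loci.annotate_concordance(locus_set)
        if config.known_loci:
            known = [tuple(r) for r in pd.read_csv(
                config.known_loci, sep=r"\s+", header=None,
                names=["chrom", "start", "end"]).itertuples(index=False)]
            _loci.annotate_novelty(locus_set, known)
        emit("loci.tsv", locus_set.to_tsv)

        stage = "ldsc"
        ldsc_res = _ldsc.cross_ldsc(t1.z, t2.z, panel.ld_score,
                                    t1.n_eff, t2.n_eff, len(panel))
        emit("ldsc.json", lambda p: Path(p).write_text(
            json.dumps(ldsc_res.__dict__, indent=1, default=float)))

        stage = "local-rg"
        local = []
        if config.run_local and len(locus_set):
            local = _localrg.analyze_loci(locus_set, panel, t1.z, t2.z,
                                          t1.n_eff, t2.n_eff,
                                          n_perm=config.n_perm_local,
                                          seed=config.seed)
            rows = [{"Chr": e.locus.chrom, "MinBP": e.locus.start_bp,
                     "MaxBP": e.locus.end_bp, "k": e.k,
                     "h2_local_1": e.h2_local_1, "p_h2_1": e.p_h2_1,
                     "h2_local_2": e.h2_local_2, "p_h2_2": e.p_h2_2,
                     "rho_local": e.rho_local, "p_rho": e.p_rho,
                     "passes": e.passes(len(locus_set))} for e in local]
            emit("local_rg.tsv", lambda p: pd.DataFrame(rows).to_csv(
                p, sep="\t", index=False, float_format="%.6g"))
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def make_report(run_dir: str | Path) -> Path:
    """Collate pipeline artifacts into one summary document (markdown-ish text)."""
    run_dir = Path(run_dir)
    lines = ["# pleiomix run summary", ""]

    def absent(name):
        lines.append(f"- {name}: ABSENT")

    venn_path = run_dir / "venn_summary.tsv"
    if venn_path.exists():
        lines.append("## Polygenic overlap (mixture model)")
        lines.append(venn_path.read_text().rstrip())
    else:
        absent("venn_summary.tsv")

    fit_path = run_dir / "mixture_fit.json"
    if fit_path.exists():
        fit = json.loads(fit_path.read_text())
        venn = fit.get("venn", {})
        cf = venn.get("concordant_fraction")
        if cf is not None:
            lines.append(f"Concordant shared-effect fraction: {cf:.2f}")
        if "aic" in fit:
            lines.append(f"AIC vs min overlap: {fit['aic']['vs_min_overlap']:.2f}; "
                         f"vs max overlap: {fit['aic']['vs_max_overlap']:.2f}")

    lines.append("")
    lines.append("## Shared loci (conjFDR < 0.05)")
    loci_path = run_dir / "loci.tsv"
    if loci_path.exists():
        df = pd.read_csv(loci_path, sep="\t")
        if len(df):
            lines.append(df.to_string(index=False))
            conc = df["Concordant"].astype(bool)
            pct = round(100.0 * conc.sum() / len(df))
            lines.append(f"Concordant effect directions: {int(conc.sum())}/{len(df)}"
                         f" ({pct}%)")
        else:
            lines.append("Zero loci reached significance.")
    else:
        absent("loci.tsv")

    lines.append("")
    lines.append("## Manhattan-style conjFDR table")
    pv = run_dir / "fdr_per_variant.tsv"
    if pv.exists():
        lines.append("per-variant -log10 conjFDR in fdr_per_variant.tsv; the "
                     "significance line sits at -log10(0.05) = 1.301")
    else:
        absent("fdr_per_variant.tsv")

    for name, title in (("ldsc.json", "Genome-wide genetic correlation (LDSC)"),
                        ("local_rg.tsv", "Local genetic correlations")):
        lines.append("")
        lines.append(f"## {title}")
        path = run_dir / name
        if path.exists():
            lines.append(path.read_text().rstrip())
        else:
            absent(name)

    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
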