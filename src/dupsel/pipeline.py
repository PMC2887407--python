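"""End-to-end analysis pipeline for a duplicated-gene study.

Runs the full workflow from one JSON config: alignment validation and
composition, within- and between-paralog divergence, sliding windows,
relative-rate tests, codon-usage bias, the branch/site/branch-site model
ladder with likelihood-ratio tests, and dS-clock dating.  Each stage
writes a fixed-name TSV/JSON artifact under the run directory, and a run
manifest records config digest and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence as dv
from . import stats as st
from .dating import clock_date
from .genetics import CodonAlignment, count_informative_sites, gc_content, read_codon_fasta
from .likelihood import CodonModel
from .models import BranchModelSpec, SiteModelSpec
from .trees import LabeledTree
from .usage import enc_table

__all__ = ["AnalysisConfig", "run_full_analysis", "PipelineError"]

logger = logging.getLogger("dupsel.pipeline")

BRANCH_LADDER = {
    "M0": lambda: None,  # resolved against the tree inside CodonModel
    "M2r": BranchModelSpec.M2r,
    "M3r": BranchModelSpec.M3r,
    "M4r": BranchModelSpec.M4r,
    "M5r": BranchModelSpec.M5r,
    "Mf": BranchModelSpec.Mf,
}
SITE_LADDER = {
    "M1": SiteModelSpec.M1,
    "M2": SiteModelSpec.M2,
    "M3": SiteModelSpec.M3,
    "M7": SiteModelSpec.M7,
    "M8": SiteModelSpec.M8,
}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (parse from JSON with
    :meth:`from_json`)."""

    alignment: str
    tree: str
    labels: str | None = None
    outdir: str = "run"
    groups: dict = field(default_factory=dict)  # {"g1": [...], "g5": [...],
    #                                              "outgroup": [...]}
    branch_models: list = field(default_factory=lambda: ["M0", "M2r", "M3r"])
    site_models: list = field(default_factory=list)
    branch_site_foreground: dict = field(default_factory=dict)
    lrt_pairs: list = field(default_factory=list)
    window_nt: int = 30
    step_nt: int = 9
    window_pairs: dict = field(default_factory=dict)  # panel -> [[a,b], ...]
    rrt_pairs: list = field(default_factory=list)     # [[seq_g1, seq_g5], ...]
    rrt_outgroup: str | None = None
    calibration: dict = field(default_factory=dict)
    seed: int = 0
    refit_branch_lengths: bool = False

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name, manifest):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc is not None:
                manifest["stages"][name] = {"status": "FAILED",
                                            "seconds": round(dt, 3),
                                            "error": str(exc)}
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(dt, 3)}
            logger.info("stage %s: done in %.2fs", name, dt)

    return _Ctx()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute every configured stage; returns the manifest dict.

    Artifacts written under ``config.outdir``: composition.tsv,
    divergence.tsv, group_comparison.tsv, window_<panel>.tsv, rrt.tsv,
    enc.tsv, branch_models.tsv, site_models.tsv, fits.json, clock.json,
    manifest.json.  On stage failure, earlier artifacts are retained and a
    FAILED marker recorded in the manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    try:
        result = _run(config, out, manifest)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return result


def _run(config: AnalysisConfig, out: Path, manifest: dict) -> dict:
    with _stage("validate", manifest):
        aln = read_codon_fasta(config.alignment)
        tree = LabeledTree.from_files(config.tree, config.labels)
        missing = [t for t in tree.taxa if t not in aln.names]
        if missing:
            raise ValueError(f"tree taxa missing from alignment: {missing}")

    groups = {k: list(v) for k, v in config.groups.items()
              if k in ("g1", "g5")}

    with _stage("composition", manifest):
        comp = gc_content(aln)
        rows = [
            {"seq_id": c.seq_id, "gc_total": c.gc_total, "gc1": c.gc1,
             "gc2": c.gc2, "gc3": c.gc3}
            for c in comp
        ]
        comp_df = pd.DataFrame(rows)
        if aln.n_sequences >= 4:
            manifest["n_informative_sites"] = count_informative_sites(aln)
        comp_df.to_csv(out / "composition.tsv", sep="\t", index=False,
                       float_format="%.6f")

    with _stage("divergence", manifest):
        div_rows = []
        group_stats: dict = {}
        for name, members in groups.items():
            if len(members) >= 2:
                g = dv.mean_divergence(aln, members)
                group_stats[name] = g
                div_rows.append(
                    {"group": name, "mean_dN": g.mean_dN,
                     "mean_dS": g.mean_dS,
                     "overall_omega": g.overall_omega}
                )
        div_df = pd.DataFrame(div_rows)
        div_df.to_csv(out / "divergence.tsv", sep="\t", index=False,
                      float_format="%.6f")

    with _stage("group_comparison", manifest):
        comp_by_id = {c.seq_id: c for c in comp}
        enc_by_id = {n: r for n, r in enc_table(aln)}
        cmp_rows = []
        if set(groups) == {"g1", "g5"} and all(
            len(v) >= 2 for v in groups.values()
        ):
            def pairwise_stat(members, attr):
                sub = aln.subset(members)
                vals = []
                for a, b, p in dv.pairwise_table(sub):
                    vals.append(getattr(p, attr))
                return vals

            per_seq = {
                "gc3": lambda m: [comp_by_id[x].gc3 for x in m],
                "enc": lambda m: [enc_by_id[x].enc for x in m],
                "dN": lambda m: pairwise_stat(m, "dN"),
                "dS": lambda m: pairwise_stat(m, "dS"),
            }
            for statname, getter in per_seq.items():
                va, vb = getter(groups["g1"]), getter(groups["g5"])
                ma, mb, tstat, p = st.compare_groups(va, vb)
                cmp_rows.append(
                    {"statistic": statname, "mean_g1": ma, "mean_g5": mb,
                     "t": tstat, "p_value": p,
                     "stars": st.significance_stars(p)}
                )
        pd.DataFrame(cmp_rows).to_csv(
            out / "group_comparison.tsv", sep="\t", index=False,
            float_format="%.6g"
        )

    with _stage("windows", manifest):
        panels = config.window_pairs or _default_window_panels(groups)
        for panel, pairs in panels.items():
            pairs = [tuple(p) for p in pairs]
            if not pairs:
                continue
            prof = dv.sliding_window(
                aln, pairs, config.window_nt, config.step_nt
            )
            pd.DataFrame(
                prof.to_rows(),
                columns=["start_1based", "end_1based", "K", "dN", "dN_dS"],
            ).to_csv(out / f"window_{panel}.tsv", sep="\t", index=False,
                     float_format="%.6f")

    with _stage("rrt", manifest):
        rrt_rows = []
        if config.rrt_outgroup and config.rrt_pairs:
            og = aln.sequence(config.rrt_outgroup)
            for a, b in config.rrt_pairs:
                r = st.tajima_rrt(aln.sequence(a), aln.sequence(b), og)
                rrt_rows.append(
                    {"seq_a": a, "seq_b": b,
                     "outgroup": config.rrt_outgroup,
                     "m1": r.m1, "m2": r.m2, "ratio": r.ratio,
                     "chi2": r.chi2, "p_value": r.p_value,
                     "stars": r.stars}
                )
        pd.DataFrame(rrt_rows).to_csv(out / "rrt.tsv", sep="\t", index=False,
                                      float_format="%.4g")

    with _stage("enc", manifest):
        enc_rows = [
            {"seq_id": n, "enc": r.enc, "gc3": comp_by_id[n].gc3,
             "n_codons": sum(r.n_codons_used.values())}
            for n, r in enc_table(aln)
        ]
        # group-level ENC on the concatenated sequences, alongside the
        # per-sequence values, since short genes make either summary noisy
        from .usage import enc as _enc

        for gname, members in groups.items():
            concat = "".join(aln.sequence(m) for m in members)
            r = _enc(concat)
            enc_rows.append(
                {"seq_id": f"<{gname} concatenated>", "enc": r.enc,
                 "gc3": float("nan"),
                 "n_codons": sum(r.n_codons_used.values())}
            )
        pd.DataFrame(enc_rows).to_csv(out / "enc.tsv", sep="\t", index=False,
                                      float_format="%.4f")

    fits: dict = {}
    with _stage("fit_models", manifest):
        fits = _fit_models(aln, tree, config)
        with open(out / "fits.json", "w") as fh:
            json.dump({k: r.to_dict() for k, r in fits.items()}, fh, indent=1)
        _write_branch_table(fits, config, out)
        _write_site_table(fits, config, out)

    with _stage("lrt", manifest):
        lrt_rows = []
        for null_name, alt_name in _lrt_pairs(config):
            if null_name not in fits or alt_name not in fits:
                continue
            r = st.lrt_from_fits(fits[null_name], fits[alt_name])
            lrt_rows.append(
                {"null": null_name, "alt": alt_name, "stat": r.stat,
                 "df": r.df, "p_value": r.p_value, "stars": r.stars,
                 "negative": r.negative}
            )
        pd.DataFrame(lrt_rows).to_csv(out / "lrt.tsv", sep="\t", index=False,
                                      float_format="%.6g")

    with _stage("clock", manifest):
        clock = _clock_stage(aln, config)
        if clock is not None:
            with open(out / "clock.json", "w") as fh:
                json.dump(clock, fh, indent=1)

    manifest["artifacts"] = sorted(
        p.name for p in out.iterdir() if p.name != "manifest.json"
    )
    return {"manifest": manifest, "fits": fits, "outdir": str(out)}


def _default_window_panels(groups: dict) -> dict:
    panels = {}
    for name, members in groups.items():
        if len(members) >= 2:
            panels[name] = [
                [members[i], members[j]]
                for i in range(len(members))
                for j in range(i + 1, len(members))
            ]
    if set(groups) == {"g1", "g5"}:
        panels["paralog"] = [
            [a, b] for a in groups["g1"] for b in groups["g5"]
        ]
    return panels


def _lrt_pairs(config: AnalysisConfig) -> list:
    if config.lrt_pairs:
        return [tuple(p) for p in config.lrt_pairs]
    ladder = [m for m in ("M0", "M2r", "M3r", "M4r", "M5r")
              if m in config.branch_models]
    pairs = list(zip(ladder, ladder[1:]))
    if "Mf" in config.branch_models and "M0" in config.branch_models:
        pairs.append(("M0", "Mf"))
    site = config.site_models
    for null, alt in (("M1", "M2"), ("M7", "M8"), ("M0", "M3")):
        if null in (site + ["M0"]) and alt in site:
            if null == "M0" and "M0" not in config.branch_models:
                continue
            pairs.append((null, alt))
    for fg_name in config.branch_site_foreground:
        if "M1" in site:
            pairs.append(("M1", f"bsA_{fg_name}"))
        if "M3" in site:
            pairs.append(("M3", f"bsB_{fg_name}"))
    return pairs


def _fit_models(aln: CodonAlignment, tree: LabeledTree,
                config: AnalysisConfig) -> dict:
    fits: dict = {}
    base = CodonModel(aln, tree)
    r0 = base.fit()
    fits["M0"] = r0
    shared_tree = r0.tree
    kw = {} if config.refit_branch_lengths else {"kappa": r0.kappa}
    obl = True if config.refit_branch_lengths else None
    for name in config.branch_models:
        if name == "M0":
            continue
        spec = BRANCH_LADDER[name]()
        model = CodonModel(aln, shared_tree, spec=spec)
        fits[name] = model.fit(optimize_branch_lengths=obl, **kw)
    for name in config.site_models:
        spec = SITE_LADDER[name]()
        model = CodonModel(aln, shared_tree, spec=spec)
        fits[name] = model.fit(optimize_branch_lengths=obl, **kw)
    for fg_name, classes in config.branch_site_foreground.items():
        for nm, ctor in (("bsA", SiteModelSpec.bsA), ("bsB", SiteModelSpec.bsB)):
            spec = ctor(tuple(classes))
            model = CodonModel(aln, shared_tree, spec=spec)
            fits[f"{nm}_{fg_name}"] = model.fit(
                optimize_branch_lengths=obl, **kw
            )
    return fits


def _write_branch_table(fits: dict, config: AnalysisConfig, out: Path) -> None:
    rows = []
    for name in ("M0", "M2r", "M3r", "M4r", "M5r", "Mf"):
        if name not in fits:
            continue
        r = fits[name]
        est = "; ".join(
            f"{k}={r.render(k)}" for k in r.params if k.startswith("omega")
        )
        if r.spec.per_branch:
            om = [v for k, v in r.params.items() if k.startswith("omega")]
            est = f"omega range {min(om):.3g}..{max(om):.3g}"
        rows.append(
            {"model": name, "p": r.n_params, "lnL": r.lnL,
             "estimates": est, "converged": r.converged}
        )
    pd.DataFrame(rows).to_csv(out / "branch_models.tsv", sep="\t",
                              index=False, float_format="%.4f")


def _write_site_table(fits: dict, config: AnalysisConfig, out: Path) -> None:
    rows = []
    for name, r in fits.items():
        if isinstance(r.spec, BranchModelSpec):
            continue
        post = r.site_posteriors()
        flagged = ",".join(f"{s}{aa}" for s, aa, _ in post.flagged_sites)
        rows.append(
            {"model": name, "p": r.n_params, "lnL": r.lnL,
             "estimates": "; ".join(
                 f"{k}={r.render(k)}" for k in r.params
                 if k.endswith("_hat") or k.startswith("beta")
             ),
             "positively_selected_sites": flagged or "none",
             "method": post.method}
        )
    pd.DataFrame(rows).to_csv(out / "site_models.tsv", sep="\t", index=False,
                              float_format="%.4f")


def _clock_stage(aln: CodonAlignment, config: AnalysisConfig) -> dict | None:
    cal = config.calibration
    if not cal:
        return None
    T = cal["T_calibration"]
    if "dS_ortholog" in cal:
        ds_o, ds_p = cal["dS_ortholog"], cal["dS_paralog"]
    else:
        a, b = cal["ortholog_pair"]
        c, d_ = cal["paralog_pair"]
        ds_o = dv.ng86_pair(aln.sequence(a), aln.sequence(b)).dS
        ds_p = dv.ng86_pair(aln.sequence(c), aln.sequence(d_)).dS
    est = clock_date(ds_o, ds_p, T)
    return {
        "dS_ortholog": est.dS_ortholog,
        "dS_paralog": est.dS_paralog,
        "T_calibration": est.T_calibration,
        "rate_per_MY": est.rate,
        "t_duplication_MYA": est.t_duplication,
        "t_duplication_rounded": est.t_rounded,
    }
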