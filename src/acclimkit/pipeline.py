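"""End-to-end orchestration of the acclimation analysis.

The run follows the analysis sequence the package implements: abundance
filter -> size-factor normalization -> PCA outlier removal -> per-gene
permutation ANOVA run separately for nonstressed and stressed samples ->
co-expression clustering of acclimation-significant genes -> eigengene
tests -> heat-stress response with cluster resampling nulls -> dampening
and mechanism classification -> stable-vs-variable two-group test ->
chlorophyll bleaching phenotype. Every stage hands off through TSV files
in the run directory and logs its parameters and row counts, so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .coexpression import UNASSIGNED, build_cluster_set, eigengene_anova
from .design import (
    ACCLIMATED_TREATMENTS,
    CountMatrix,
    ExperimentDesign,
    read_counts,
    read_design,
    read_table,
    write_table,
)
from .normalize import (
    drop_samples,
    filter_contigs,
    flag_outlier_samples,
    log_transform,
    normalize,
    size_factors,
)
from .permtest import permutation_pvalues, select_significant, two_group_test
from .phenotype import (
    chlorophyll_density_table,
    fit_area_curve,
    phenotype_anova,
    retained_fraction,
)
from .simulate import (
    GeneratorConfig,
    artifact_tank_samples,
    inject_outliers,
    simulate_counts,
    simulate_design,
    simulate_phenotype,
)
from .stress import (
    arm_means,
    classify_mechanism,
    cluster_null_test,
    dampening_index,
    gene_log2fc,
)

log = logging.getLogger("acclimkit")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns a summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    t0 = time.time()
    log.info("acclimkit %s run; config: %s", __version__, vars(config))
    summary: dict = {"version": __version__, "seed": config.seed}

    def stage(name):
        log.info("stage %s ...", name)
        return time.time()

    # ---- inputs -----------------------------------------------------
    try:
        t = stage("inputs")
        if config.simulate:
            gen = GeneratorConfig(**{"seed": config.stage_seed("simulate"), **config.generator})
            design = simulate_design(gen)
            counts, truth = simulate_counts(design, gen)
            artifact: list[str] = []
            if config.inject_artifact and 2 in gen.days:
                artifact = artifact_tank_samples(design, day=2)
                # scale 3 on 30% of genes: strong enough for an unambiguous
                # PCA artifact, mild enough that the affected genes survive
                # the SD<mean abundance filter (a 10x spike mostly does not)
                counts = inject_outliers(
                    counts, artifact, scale=3.0, fraction_genes=0.3,
                    seed=config.stage_seed("simulate") + 1,
                )
            phen_records, standards, phen_truth = simulate_phenotype(design, gen)
            write_table(design, out / "design.tsv")
            write_table(counts, out / "counts.tsv")
            write_table(truth.genes, out / "truth_genes.tsv")
            write_table(truth.samples.assign(outlier=truth.samples.index.isin(artifact)),
                        out / "truth_samples.tsv")
            write_table(phen_records, out / "phenotype_records.tsv")
            standards.to_csv(out / "standards.tsv", sep="\t", index=False)
            write_table(phen_truth.reset_index().set_index("colony_id"),
                        out / "truth_phenotype.tsv")
            summary["simulated"] = True
            summary["artifact_samples"] = artifact
        else:
            counts = read_counts(config.counts)
            design = read_design(config.design)
            counts = counts.align_to(design)
            phen_records = (
                read_table(config.phenotype) if config.phenotype else None
            )
            standards = (
                pd.read_csv(config.standards, sep="\t") if config.standards else None
            )
        counts = counts.align_to(design)
        summary["n_samples"] = design.n_samples
        summary["n_genes_input"] = counts.shape[0]
        log.info("inputs: %d genes x %d samples (%.1fs)",
                 counts.shape[0], design.n_samples, time.time() - t)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # ---- filter + normalize -----------------------------------------
    try:
        t = stage("normalize")
        counts_f, filt_report = filter_contigs(counts, min_mean=config.min_mean)
        write_table(filt_report.table, out / "filter_report.tsv")
        sf = size_factors(counts_f)
        norm = normalize(counts_f, sf)
        write_table(sf.to_frame(), out / "size_factors.tsv")
        write_table(norm.values, out / "normalized.tsv")
        summary["n_genes_filtered"] = counts_f.shape[0]
        log.info("filter kept %d/%d genes (%.1fs)",
                 counts_f.shape[0], counts.shape[0], time.time() - t)
    except Exception as exc:
        raise StageError("normalize", exc) from exc

    # ---- QC: outlier flag + drop ------------------------------------
    try:
        t = stage("qc")
        qc = flag_outlier_samples(norm, design, z_threshold=config.z_threshold,
                                  pseudocount=config.pseudocount)
        write_table(qc.table, out / "outlier_report.tsv")
        flagged = list(qc.flagged)
        if flagged:
            counts_f = drop_samples(counts_f, flagged)
            design = design.subset([s for s in design.sample_ids if s not in flagged])
            sf = size_factors(counts_f)
            norm = normalize(counts_f, sf)
        summary["n_outliers_flagged"] = len(flagged)
        summary["outlier_samples"] = flagged
        log.info("qc flagged %d samples (%.1fs)", len(flagged), time.time() - t)
    except Exception as exc:
        raise StageError("qc", exc) from exc

    norm_log = log_transform(norm, pseudocount=config.pseudocount)

    # ---- per-condition permutation ANOVA ----------------------------
    anova_sig = {}
    for cond in ("nonstressed", "stressed"):
        try:
            t = stage(f"anova_{cond}")
            dsub = design.subset(f"condition == '{cond}'")
            table = permutation_pvalues(
                norm_log.loc[:, dsub.sample_ids], dsub,
                n_permutations=config.n_permutations,
                seed=config.stage_seed(f"anova_{cond}"),
            )
            write_table(table, out / f"anova_{cond}.tsv")
            sig = select_significant(table, term="treatment", alpha=config.alpha)
            anova_sig[cond] = sig
            summary[f"n_significant_{cond}"] = int(len(sig))
            log.info("anova %s: %d/%d significant at FDR %.3g (%.1fs)",
                     cond, len(sig), table.shape[0], config.alpha, time.time() - t)
        except Exception as exc:
            raise StageError(f"anova_{cond}", exc) from exc

    # ---- clustering of stressed-significant genes -------------------
    clusters = None
    try:
        t = stage("cluster")
        sig = anova_sig["stressed"]
        if len(sig) >= config.min_cluster_size:
            dstress = design.subset("condition == 'stressed'")
            expr = norm_log.loc[sig, dstress.sample_ids]
            clusters = build_cluster_set(
                expr, rho_threshold=config.rho_threshold,
                min_size=config.min_cluster_size,
            )
            write_table(clusters.membership.to_frame(), out / "cluster_membership.tsv")
            write_table(clusters.eigengenes, out / "eigengenes.tsv")
            write_table(clusters.variance_explained.to_frame(), out / "variance_explained.tsv")
            eig_tests = {}
            for lab in clusters.labels:
                eig_tests[lab] = eigengene_anova(
                    clusters.eigengenes.loc[lab], dstress,
                    n_permutations=config.n_permutations,
                    seed=config.stage_seed("cluster"),
                )
            if eig_tests:
                write_table(pd.DataFrame(eig_tests).T, out / "eigengene_anova.tsv")
            summary["n_clusters"] = len(clusters.labels)
            summary["cluster_sizes"] = {
                lab: int(n) for lab, n in clusters.sizes().items()
            }
            summary["n_unassigned"] = int((clusters.membership == UNASSIGNED).sum())
        else:
            summary["n_clusters"] = 0
            log.info("too few significant genes (%d) to cluster", len(sig))
        log.info("cluster stage done (%.1fs)", time.time() - t)
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    # ---- heat-stress response + cluster nulls -----------------------
    try:
        t = stage("respond")
        lfc_all = gene_log2fc(norm, design, pseudocount=config.pseudocount)
        write_table(lfc_all.to_frame(), out / "log2fc_all.tsv")
        null_rows = []
        if clusters is not None:
            for lab in clusters.labels:
                res = cluster_null_test(
                    lfc_all, clusters.members(lab),
                    n_draws=config.n_draws,
                    seed=config.stage_seed("respond"),
                    label=lab,
                )
                null_rows.append(
                    {
                        "cluster": lab,
                        "observed_mean_log2fc": res.observed,
                        "null_mean": res.null_mean,
                        "p": res.p_value,
                        "envelope_lo": res.envelope[0],
                        "envelope_hi": res.envelope[1],
                        "n_draws": res.n_draws,
                    }
                )
        if null_rows:
            cluster_null = pd.DataFrame(null_rows).set_index("cluster")
            write_table(cluster_null, out / "cluster_null_tests.tsv")
            summary["cluster_null_p"] = dict(zip(cluster_null.index, cluster_null["p"]))
        log.info("respond stage done (%.1fs)", time.time() - t)
    except Exception as exc:
        raise StageError("respond", exc) from exc

    # ---- dampening + mechanism --------------------------------------
    try:
        t = stage("dampening")
        if clusters is not None and len(clusters.labels) > 0:
            genes = clusters.membership.index[clusters.membership != UNASSIGNED]
            damp_rows, mech = [], {}
            ctrl_lfc = gene_log2fc(
                norm, design,
                stratum=f"treatment == 'control29' and ({config.dampening_stratum})",
                pseudocount=config.pseudocount,
            ).loc[genes]
            base_c, stress_c = arm_means(norm, design, "treatment == 'control29'")
            for trt in ACCLIMATED_TREATMENTS:
                if trt not in set(design.table["treatment"]):
                    continue
                acc_lfc = gene_log2fc(
                    norm, design,
                    stratum=f"treatment == '{trt}' and ({config.dampening_stratum})",
                    pseudocount=config.pseudocount,
                ).loc[genes]
                res = dampening_index(
                    ctrl_lfc, acc_lfc, seed=config.stage_seed("respond") + 1
                )
                damp_rows.append(
                    {
                        "treatment": trt,
                        "slope": res.slope,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "ratio": res.ratio,
                        "dampened": res.dampened,
                        "n_genes": res.n_genes,
                    }
                )
                base_a, stress_a = arm_means(norm, design, f"treatment == '{trt}'")
                mech[trt] = classify_mechanism(
                    base_c.loc[genes], base_a.loc[genes],
                    stress_c.loc[genes], stress_a.loc[genes],
                    tau_baseline=config.tau_baseline,
                    tau_response=config.tau_response,
                    pseudocount=config.pseudocount,
                )
            if damp_rows:
                damp = pd.DataFrame(damp_rows).set_index("treatment")
                write_table(damp, out / "dampening.tsv")
                summary["dampening_slope"] = dict(zip(damp.index, damp["slope"]))
            if mech:
                mech_df = pd.DataFrame(mech)
                write_table(mech_df, out / "mechanism_labels.tsv")
                summary["mechanism_counts"] = {
                    trt: mech_df[trt].value_counts().to_dict() for trt in mech_df
                }
        log.info("dampening stage done (%.1fs)", time.time() - t)
    except Exception as exc:
        raise StageError("dampening", exc) from exc

    # ---- stable vs variable -----------------------------------------
    try:
        t = stage("two_group")
        for cond in ("nonstressed", "stressed"):
            ids_a = design.subset(
                f"treatment == 'stable31' and day in (7, 11) and condition == '{cond}'"
            ).sample_ids
            ids_b = design.subset(
                f"treatment == 'variable29_33' and day in (7, 11) and condition == '{cond}'"
            ).sample_ids
            if len(ids_a) < 2 or len(ids_b) < 2:
                continue
            res = two_group_test(
                norm_log, design, list(ids_a), list(ids_b),
                n_permutations=config.n_permutations,
                seed=config.stage_seed("two_group"),
            )
            write_table(res, out / f"stable_vs_variable_{cond}.tsv")
            summary[f"n_stable_vs_variable_{cond}"] = int(
                (res["q"] <= config.two_group_alpha).sum()
            )
        log.info("two-group stage done (%.1fs)", time.time() - t)
    except Exception as exc:
        raise StageError("two_group", exc) from exc

    # ---- phenotype --------------------------------------------------
    try:
        t = stage("phenotype")
        if config.simulate or (config.phenotype and config.standards):
            curve = fit_area_curve(standards[["weight_gain", "area"]])
            dens = chlorophyll_density_table(phen_records, curve)
            # the full (pre-QC) design covers every phenotyped branch
            gen_kwargs = {"seed": 0, **config.generator}
            full_design = (
                simulate_design(GeneratorConfig(**gen_kwargs))
                if config.simulate
                else read_design(config.design)
            )
            write_table(dens, out / "chl_density.tsv")
            frac = retained_fraction(dens, full_design)
            write_table(frac.reset_index().set_index("colony_id"), out / "retained_fraction.tsv")
            flat = frac.reset_index()
            anova = phenotype_anova(
                flat["retained_fraction"],
                flat[["treatment", "day"]],
                exclude_day0=config.exclude_day0,
                n_permutations=config.n_permutations,
                seed=config.stage_seed("phenotype"),
            )
            anova.to_frame("value").to_csv(out / "phenotype_anova.tsv", sep="\t")
            summary["phenotype_anova"] = {
                k: float(v) for k, v in anova.items() if k.startswith(("p_", "F_"))
            }
            summary["area_curve"] = {
                "slope": curve.slope, "intercept": curve.intercept, "r2": curve.r_squared,
            }
        log.info("phenotype stage done (%.1fs)", time.time() - t)
    except Exception as exc:
        raise StageError("phenotype", exc) from exc

    summary["elapsed_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    log.info("run complete in %.1fs", summary["elapsed_s"])
    return summary
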