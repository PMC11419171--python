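"""End-to-end pipeline driver.

Stages (each reads its inputs from, and writes its artifacts to, the run
directory, so they can be invoked individually from the CLI or all at
once): simulate -> features -> cluster -> characterize -> transfer ->
assoc -> meta -> report. Identical config + seeds give byte-identical
artifacts; every stage writes a manifest with input/output hashes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .assoc import ld_expand, run_stratified_assoc
from .characterize import enrichment_table
from .cluster import (MethodParams, baseline_cluster, model_sweep,
                      select_model, spectral_cluster)
from .config import PipelineConfig, SimulateSection
from .features import (FeatureCatalog, PhenotypeMatrix, case_status,
                       default_catalog, extract_features, prevalence_filter)
from .meta import meta_analyze, negative_control, significance_summary
from .simulate import (SimConfig, VariantSpec, block_prevalence,
                       simulate_cohort)
from .transfer import TransferModel, knn_assign

__all__ = ["PipelineError", "run_pipeline", "build_variant_specs",
           "build_sim_configs"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _manifest(outdir: Path, stage: str, seed, inputs, outputs) -> None:
    eio.write_manifest(outdir / f"manifest.{stage}.json", stage, seed,
                       inputs, outputs)


# ---------------------------------------------------------------------------
# synthetic inputs
# ---------------------------------------------------------------------------

def build_variant_specs(sim: SimulateSection) -> list[VariantSpec]:
    """Candidate-locus panel: ``n_lead_snps`` leads spaced well past the
    LD window (lead 1 carries a shared effect across all subtypes, lead 2
    an effect confined to subtype 0, the rest are null), plus LD tags
    copied from the first leads with per-subject re-draw noise."""
    K = sim.n_subtypes
    lo, hi = sim.maf_range
    mafs = np.linspace(lo, hi, sim.n_lead_snps)
    specs: list[VariantSpec] = []
    for i in range(sim.n_lead_snps):
        chrom = str(i % 22 + 1)
        pos = 10_000_000 + (i // 22) * 5_000_000
        if i == 0:
            beta = tuple([float(np.log(sim.global_or))] * K)
            mafs[i] = 0.3  # causal leads at a common frequency
        elif i == 1:
            beta = tuple([float(np.log(sim.subtype_or))] + [0.0] * (K - 1))
            mafs[i] = 0.3
        else:
            beta = tuple([0.0] * K)
        specs.append(VariantSpec(
            rsid=f"rs{1000 + i}", chrom=chrom, pos=pos, maf=float(mafs[i]),
            beta_k=beta, locus_label=f"locus_{i + 1:02d}"))
    for t in range(min(sim.n_tag_snps, sim.n_lead_snps)):
        lead = specs[t]
        specs.append(VariantSpec(
            rsid=f"rs{9000 + t}", chrom=lead.chrom, pos=lead.pos + 100_000,
            maf=lead.maf, beta_k=tuple([0.0] * K), locus_label=lead.locus_label,
            tag_of=lead.rsid, tag_flip=sim.tag_flip))
    return specs


def build_sim_configs(sim: SimulateSection, seed: int
                      ) -> tuple[SimConfig, SimConfig, list[str]]:
    """(derivation, genotyped-cohort) generator configs sharing the same
    planted structure, and the simulated feature-name list."""
    cat = default_catalog()
    non_anat = [e.feature_name for e in cat.entries
                if e.group != "anatomical_subtype"]
    names = non_anat[:sim.n_cluster_features]
    p_jk, p_j0 = block_prevalence(sim.n_cluster_features, sim.n_subtypes,
                                  sim.p_high, sim.p_low)
    # plant anatomical-site flags for characterization (cases only: these
    # are themselves endometriosis codes, so controls must never emit them)
    if sim.n_subtypes >= 3:
        anat = [("endometriosis_uterus", 1), ("endometriosis_peritoneum", 2),
                ("endometriosis_unspecified", sim.n_subtypes - 1)]
        extra = np.full((len(anat), sim.n_subtypes), 0.05)
        for r, (fname, k) in enumerate(anat):
            extra[r, k] = 0.35
            names.append(fname)
        p_jk = np.vstack([p_jk, extra])
        p_j0 = np.concatenate([p_j0, np.zeros(len(anat))])
    specs = build_variant_specs(sim)
    derivation = SimConfig(
        n_controls=0,
        n_cases_per_subtype=[sim.derivation_cases_per_subtype] * sim.n_subtypes,
        feature_prevalence=p_jk, control_feature_prevalence=p_j0,
        variant_specs=[], strata=[tuple(s) for s in sim.strata],
        feature_names=names, dataset="DERIV",
        icd_sensitivity=sim.icd_sensitivity, seed=seed,
    )
    cohort = SimConfig(
        n_controls=sim.cohort_controls,
        n_cases_per_subtype=[sim.cohort_cases_per_subtype] * sim.n_subtypes,
        feature_prevalence=p_jk, control_feature_prevalence=p_j0,
        variant_specs=specs, strata=[tuple(s) for s in sim.strata],
        feature_names=names, dataset="GENO",
        icd_sensitivity=sim.icd_sensitivity, seed=seed + 1,
    )
    return derivation, cohort, names


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim = config.simulate
    if sim is None:
        raise ValueError("config has no simulate section")
    seed = config.seeds["simulate"]
    dcfg, ccfg, _ = build_sim_configs(sim, seed)
    deriv = simulate_cohort(dcfg)
    cohort = simulate_cohort(ccfg)
    eio.write_subjects(deriv.subjects, outdir / "derivation.subjects.tsv")
    eio.write_icd(deriv.icd, outdir / "derivation.icd.tsv")
    eio.write_truth_json(deriv.truth, outdir / "derivation.truth.json")
    eio.write_subjects(cohort.subjects, outdir / "cohort.subjects.tsv")
    eio.write_icd(cohort.icd, outdir / "cohort.icd.tsv")
    eio.write_truth_json(cohort.truth, outdir / "cohort.truth.json")
    eio.write_vcf(cohort.genotypes, outdir / "cohort.vcf")
    eio.write_dosage_tsv(cohort.genotypes, outdir / "cohort.dosage.tsv")
    leads = cohort.genotypes.variants[
        [s.tag_of is None for s in ccfg.variant_specs]]
    eio.write_locus_list(leads.rename(columns={})[["rsid", "chrom", "pos",
                                                   "locus_label"]],
                         outdir / "loci.tsv")
    default_catalog().to_yaml(outdir / "catalog.yaml")
    _manifest(outdir, "simulate", seed, [],
              [outdir / p for p in ("derivation.subjects.tsv", "derivation.icd.tsv",
                                    "cohort.subjects.tsv", "cohort.icd.tsv",
                                    "cohort.vcf", "cohort.dosage.tsv", "loci.tsv")])


def _catalog(config: PipelineConfig, outdir: Path) -> FeatureCatalog:
    if config.catalog_path:
        return FeatureCatalog.from_yaml(config.catalog_path)
    p = outdir / "catalog.yaml"
    if p.exists():
        return FeatureCatalog.from_yaml(p)
    return default_catalog()


def _derivation_inputs(config, outdir):
    subj = config.subjects_path or outdir / "derivation.subjects.tsv"
    icd = config.icd_path or outdir / "derivation.icd.tsv"
    return eio.read_subjects(subj), eio.read_icd(icd)


def stage_features(config: PipelineConfig, outdir: Path) -> None:
    subjects, icd = _derivation_inputs(config, outdir)
    catalog = _catalog(config, outdir)
    status = case_status(icd, subjects)
    case_ids = status.index[status == "case"].tolist()
    if not case_ids:
        raise ValueError("no endometriosis cases in derivation cohort")
    X39 = extract_features(icd, catalog, subject_ids=case_ids)
    X17 = prevalence_filter(X39, np.ones(len(case_ids), bool), catalog,
                            config.min_prevalence)
    eio.write_feature_matrix(X39, outdir / "features.full.tsv")
    eio.write_feature_matrix(X17, outdir / "features.cluster.tsv")
    status.to_frame().to_csv(outdir / "case_status.tsv", sep="\t")
    _manifest(outdir, "features", None,
              [outdir / "derivation.icd.tsv"],
              [outdir / "features.full.tsv", outdir / "features.cluster.tsv"])


def stage_cluster(config: PipelineConfig, outdir: Path) -> None:
    X17 = eio.read_feature_matrix(outdir / "features.cluster.tsv")
    seed = config.seeds["cluster"]
    base = MethodParams(affinity_neighbors=config.affinity_neighbors,
                        eps=config.dbscan_eps,
                        min_samples=config.dbscan_min_samples,
                        linkage=config.linkage, n_restarts=config.n_restarts,
                        seed=seed)
    sweep = model_sweep(X17, methods=config.methods,
                        K_range=range(config.k_min, config.k_max + 1),
                        seed=seed, base_params=base)
    sweep.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
    sel = select_model(sweep, max_clusters=config.k_max)
    params = MethodParams(method=sel.method, K=sel.K,
                          affinity_neighbors=config.affinity_neighbors,
                          eps=config.dbscan_eps,
                          min_samples=config.dbscan_min_samples,
                          linkage=config.linkage, n_restarts=config.n_restarts,
                          seed=seed)
    if sel.method == "spectral":
        run, embedding = spectral_cluster(X17, params)
        emb = pd.DataFrame(embedding,
                           columns=[f"eigvec{i + 1}" for i in range(sel.K)])
        emb.insert(0, "subject_id", X17.subject_ids)
        emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
    else:
        run = baseline_cluster(X17, params)
    pd.DataFrame({"subject_id": X17.subject_ids, "cluster": run.labels}).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    (outdir / "model_selection.json").write_text(json.dumps({
        "method": sel.method, "K": sel.K, "rule": sel.rule,
        "justification": sel.justification,
        "silhouette": run.silhouette, "distortion": run.distortion,
        "evenness": run.evenness}, indent=1))
    _manifest(outdir, "cluster", seed, [outdir / "features.cluster.tsv"],
              [outdir / "sweep.tsv", outdir / "clusters.tsv",
               outdir / "model_selection.json"])


def stage_characterize(config: PipelineConfig, outdir: Path) -> None:
    X17 = eio.read_feature_matrix(outdir / "features.cluster.tsv")
    X39 = eio.read_feature_matrix(outdir / "features.full.tsv")
    catalog = _catalog(config, outdir)
    labels = pd.read_csv(outdir / "clusters.tsv", sep="\t",
                         dtype={"subject_id": str})["cluster"].to_numpy()
    groups = catalog.groups()
    anat_names = [f for f in X39.feature_names
                  if groups.get(f) == "anatomical_subtype"]
    extra = X39.select_features(anat_names) if anat_names else None
    enr = enrichment_table(X17, labels, extra_flags=extra)
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    _manifest(outdir, "characterize", None,
              [outdir / "features.cluster.tsv", outdir / "clusters.tsv"],
              [outdir / "enrichment.tsv"])


def _cohort_inputs(config, outdir):
    subj = config.cohort_subjects_path or outdir / "cohort.subjects.tsv"
    icd = config.cohort_icd_path or outdir / "cohort.icd.tsv"
    return eio.read_subjects(subj), eio.read_icd(icd)


def stage_transfer(config: PipelineConfig, outdir: Path) -> None:
    X17 = eio.read_feature_matrix(outdir / "features.cluster.tsv")
    labels = pd.read_csv(outdir / "clusters.tsv", sep="\t")["cluster"].to_numpy()
    model = TransferModel(X17, labels, k=config.knn_k)
    model.to_frame().to_csv(outdir / "transfer_model.tsv", sep="\t")
    subjects, icd = _cohort_inputs(config, outdir)
    catalog = _catalog(config, outdir)
    status = case_status(icd, subjects)
    case_ids = status.index[status == "case"].tolist()
    testX = extract_features(icd, catalog, subject_ids=case_ids)
    testX = testX.select_features(X17.feature_names)
    assign = knn_assign(model, testX)
    assign.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    _manifest(outdir, "transfer", None,
              [outdir / "features.cluster.tsv", outdir / "clusters.tsv",
               outdir / "cohort.icd.tsv"],
              [outdir / "assignments.tsv", outdir / "transfer_model.tsv"])


def _read_genotypes(config, outdir):
    if config.genotypes_path:
        p = Path(config.genotypes_path)
        return eio.read_vcf(p) if p.suffix == ".vcf" else eio.read_dosage_tsv(p)
    p = outdir / "cohort.dosage.tsv"
    if p.exists():
        return eio.read_dosage_tsv(p)
    return eio.read_vcf(outdir / "cohort.vcf")


def stage_assoc(config: PipelineConfig, outdir: Path) -> None:
    subjects, icd = _cohort_inputs(config, outdir)
    G = _read_genotypes(config, outdir)
    loci = eio.read_locus_list(config.locus_list_path or outdir / "loci.tsv")
    status = case_status(icd, subjects)
    case_ids = status.index[status == "case"].tolist()
    control_ids = status.index[status == "control"].tolist()
    assign = pd.read_csv(outdir / "assignments.tsv", sep="\t",
                         dtype={"subject_id": str})
    labels = assign.set_index("subject_id")["cluster"]

    # LD reference: the cohort's control genotypes stand in for an
    # external reference panel
    ref = G.subset_subjects([s for s in control_ids if s in set(G.subject_ids)])
    locus_set = ld_expand(ref, [r for r in loci["rsid"] if r in set(G.rsids)],
                          window=config.ld_window, r2_min=config.r2_min)
    locus_set.table.to_csv(outdir / "locus_set.tsv", sep="\t", index=False)

    phenotypes: dict[str, list[str]] = {}
    for c in sorted(labels.unique()):
        phenotypes[f"cluster_{c}"] = labels.index[labels == c].tolist()
    phenotypes["positive_control"] = list(labels.index)
    neg = negative_control(labels, subjects.set_index("subject_id")["dataset"],
                           seed=config.seeds["negative_control"])
    for c in sorted(neg.unique())[:config.n_negative_controls]:
        phenotypes[f"negative_control_{c}"] = neg.index[neg == c].tolist()

    results = run_stratified_assoc(
        G, subjects, phenotypes, control_ids,
        test_rsids=locus_set.all_rsids, n_pcs=config.n_pcs,
        beta_method=config.beta_method)
    eio.write_summary_stats(results, outdir / "assoc_stats.tsv")
    _manifest(outdir, "assoc", None,
              [outdir / "assignments.tsv", outdir / "loci.tsv"],
              [outdir / "locus_set.tsv", outdir / "assoc_stats.tsv"])


def stage_meta(config: PipelineConfig, outdir: Path) -> None:
    results = eio.read_summary_stats(outdir / "assoc_stats.tsv")
    meta = meta_analyze(results)
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    _manifest(outdir, "meta", None, [outdir / "assoc_stats.tsv"],
              [outdir / "meta.tsv"])


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    from .assoc import LocusSet

    meta = pd.read_csv(outdir / "meta.tsv", sep="\t", dtype={"variant": str})
    locus_set = LocusSet(pd.read_csv(outdir / "locus_set.tsv", sep="\t",
                                     dtype={"rsid": str, "lead_rsid": str,
                                            "chrom": str}))
    summary = significance_summary(meta, locus_set,
                                   bonferroni_n=config.bonferroni_n,
                                   gw_alpha=config.gw_alpha)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    lines = ["# Cluster-stratified association summary", "",
             summary.to_markdown(index=False)]
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    _manifest(outdir, "report", None,
              [outdir / "meta.tsv", outdir / "locus_set.tsv"],
              [outdir / "summary.tsv", outdir / "summary.md"])


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "cluster": stage_cluster,
    "characterize": stage_characterize,
    "transfer": stage_transfer,
    "assoc": stage_assoc,
    "meta": stage_meta,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, outdir, stages=None) -> Path:
    """Run the configured stages in order (all of them by default; the
    simulate stage is skipped automatically in real-data mode). A stage
    failure raises :class:`PipelineError` naming the stage; artifacts
    written before the failure are retained."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
        if config.simulate is None:
            stages.remove("simulate")
    for name in stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        try:
            STAGES[name](config, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc
    return outdir
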