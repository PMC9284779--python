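"""Configuration-driven orchestration of the staged analysis.

``run_stage`` executes QC -> block detection (or imported block definitions,
for the detect-in-stage-1 / apply-to-stage-2 design) -> EM phasing ->
case-control association, and optionally the quantitative-trait pathway;
``run_meta`` pools two stages' per-unit results with fixed- and
random-effects models.  Every run records its seed and a hash of its
configuration so result files are reproducible and attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, ld, phase, qc
from .simulate import SimulatedCohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one stage run, with the canonical defaults."""

    seed: int = 0
    out_dir: str = "results/stage"
    # QC
    call_rate_variant: float = 0.98
    maf: float = 0.01
    call_rate_sample: float = 0.98
    hwe_p: float = 1e-4
    ibd_z0: float = 0.8
    check_ibd: bool = False
    # blocks
    max_markers: int = 15
    max_span_bp: int = 160_000
    strong_upper: float = 0.98
    strong_lower: float = 0.70
    recomb_upper: float = 0.90
    informative_fraction: float = 0.95
    # EM
    em_max_iter: int = 50
    em_tol: float = 1e-4
    min_hap_freq: float = 0.01
    # association
    n_pcs: int = 10
    use_pcs: bool = False
    run_traits: bool = False
    trait_covariates: list[str] = field(
        default_factory=lambda: ["sex", "age", "pmi", "rin"])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class StageResults:
    config: PipelineConfig
    variant_keep: np.ndarray
    sample_keep: np.ndarray
    qc_report: qc.QCReport
    blockset: ld.BlockSet
    hapsets: list[phase.HaplotypeSet]
    assoc_tables: dict[str, pd.DataFrame]
    block_table: pd.DataFrame
    trait_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def block_definitions(blockset: ld.BlockSet, variants: pd.DataFrame) -> list[dict]:
    """Serializable block definitions (by position) for reuse on new data."""
    return [{"start": b.start, "stop": b.stop,
             "members": [int(variants.iloc[i]["pos"]) for i in b.variant_indices]}
            for b in blockset]


def apply_block_definitions(defs: list[dict], variants: pd.DataFrame
                            ) -> ld.BlockSet:
    """Map imported block definitions onto a dataset's variants by position."""
    pos_to_idx = {int(p): i for i, p in enumerate(variants["pos"])}
    blocks = []
    for d in defs:
        idx = sorted(pos_to_idx[p] for p in d["members"] if p in pos_to_idx)
        if len(idx) >= 2:
            blocks.append(ld.Block(idx, int(variants.iloc[idx[0]]["pos"]),
                                   int(variants.iloc[idx[-1]]["pos"])))
        else:
            logger.warning("imported block %s-%s has <2 matching variants",
                           d["start"], d["stop"])
    return ld.BlockSet(blocks)


def run_stage(
    cohort: SimulatedCohort | tuple,
    config: PipelineConfig,
    imported_blocks: list[dict] | None = None,
    write: bool = False,
) -> StageResults:
    """One full stage: QC, blocks, phasing, association (traits optional).

    ``cohort`` is either a :class:`SimulatedCohort` or a tuple
    (variants, genotypes, status, covariates, traits_or_None).
    """
    if isinstance(cohort, SimulatedCohort):
        variants, genotypes = cohort.variants, cohort.genotypes
        status, covariates = cohort.status, cohort.covariates
        traits = cohort.traits
    else:
        variants, genotypes, status, covariates, traits = cohort

    vkeep, skeep, report = qc.run_qc_chain(
        genotypes, variant_table=variants,
        call_rate_variant=config.call_rate_variant, maf=config.maf,
        call_rate_sample=config.call_rate_sample, hwe_p=config.hwe_p,
        ibd_z0=config.ibd_z0, check_ibd=config.check_ibd,
    )
    g = genotypes[np.ix_(skeep, vkeep)]
    v = variants.loc[vkeep].reset_index(drop=True)
    st = np.asarray(status)[skeep]
    cov_df = covariates.loc[skeep].reset_index(drop=True)
    tr = traits.loc[skeep].reset_index(drop=True) if traits is not None else None

    order = np.argsort(v["pos"].to_numpy(), kind="stable")
    g, v = g[:, order], v.iloc[order].reset_index(drop=True)

    if imported_blocks is not None:
        blockset = apply_block_definitions(imported_blocks, v)
    else:
        blockset = ld.gabriel_blocks(
            g, v["pos"].to_numpy(),
            max_markers=config.max_markers, max_span_bp=config.max_span_bp,
            strong_upper=config.strong_upper, strong_lower=config.strong_lower,
            recomb_upper=config.recomb_upper,
            informative_fraction=config.informative_fraction,
        )

    pcs = qc.pca_covariates(g, config.n_pcs) if config.use_pcs else None

    hapsets, assoc_tables, block_rows, trait_tables = [], {}, [], {}
    for k, block in enumerate(blockset, 1):
        bid = f"B{k}"
        sub = g[:, block.variant_indices]
        hs = phase.em_haplotype_freqs(sub, block_id=bid,
                                      max_iter=config.em_max_iter,
                                      tol=config.em_tol)
        hs = phase.prune_rare(hs, config.min_hap_freq)
        hapsets.append(hs)
        dosages = phase.haplotype_dosages(hs, n_samples=len(st))
        kept = phase.retained_indices(hs)
        labels = hs.labels()
        ref = hs.reference_index()
        res = assoc.block_association(
            dosages[:, kept], st, [labels[i] for i in kept],
            covariates=pcs,
            reference_index=int(np.flatnonzero(kept == ref)[0]),
            block_id=bid,
        )
        assoc_tables[bid] = assoc.results_frame(res)
        block_rows.append({
            "block_id": bid, "start": block.start, "stop": block.stop,
            "n_snps": block.n_snps,
            "p_lrt": res[0].p_lrt, "df": res[0].df,
        })
        if config.run_traits and tr is not None:
            from . import traits as trait_mod

            cov_cols = [c for c in config.trait_covariates
                        if c in cov_df.columns]
            for tname in tr.columns:
                resid = trait_mod.residualize(
                    tr[tname].to_numpy(float), cov_df[cov_cols])
                z, _ = trait_mod.zscore_combine({"all": resid})
                rows = trait_mod.subhap_trait_regression(
                    z, dosages[:, kept], [labels[i] for i in kept],
                    int(np.flatnonzero(kept == ref)[0]), trait_name=tname)
                trait_tables.setdefault(bid, []).extend(rows)
    block_table = pd.DataFrame(block_rows)
    if len(block_table):
        block_table["fdr_q"] = assoc.bh_fdr(block_table["p_lrt"])

    from .traits import trait_results_frame

    trait_frames = {bid: trait_results_frame(rows)
                    for bid, rows in trait_tables.items()}
    results = StageResults(config, vkeep, skeep, report, blockset, hapsets,
                           assoc_tables, block_table, trait_frames)
    if write:
        _write_stage(results, v)
    return results


def _write_stage(results: StageResults, variants: pd.DataFrame) -> None:
    out = Path(results.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": results.config.seed,
            "config_hash": results.config.config_hash()}
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    results.config.to_yaml(out / "config.yaml")
    results.qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t",
                                        index=False)
    results.block_table.to_csv(out / "blocks.tsv", sep="\t", index=False)
    (out / "block_definitions.json").write_text(
        json.dumps(block_definitions(results.blockset, variants)))
    for bid, table in results.assoc_tables.items():
        table.to_csv(out / f"assoc_{bid}.tsv", sep="\t", index=False)
    for bid, table in results.trait_tables.items():
        table.to_csv(out / f"trait_{bid}.tsv", sep="\t", index=False)


def run_meta(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Pool two stages' haplotype rows (keyed by id) with FE + RE models.

    Units present in only one stage are emitted unpooled with a
    ``missing_in`` flag.
    """
    from .meta import StudyEffect, dersimonian_laird, fixed_effects_iv

    a = results_a[results_a["type"] == "haplotype"].set_index("id")
    b = results_b[results_b["type"] == "haplotype"].set_index("id")
    rows = []
    for uid in sorted(set(a.index) | set(b.index)):
        row = {"id": uid}
        studies = []
        for name, df in (("stage1", a), ("stage2", b)):
            if uid in df.index:
                r = df.loc[uid]
                studies.append(StudyEffect(name, b=float(r["beta"]),
                                           se=float(r["se"])))
            else:
                row["missing_in"] = name
        if len(studies) >= 1:
            fe = fixed_effects_iv(studies)
            re = dersimonian_laird(studies)
            row |= {"fe_or": fe.OR, "fe_ci_low": fe.ci95[0],
                    "fe_ci_high": fe.ci95[1], "fe_p": fe.p,
                    "re_or": re.OR, "re_ci_low": re.ci95[0],
                    "re_ci_high": re.ci95[1], "re_p": re.p,
                    "q": fe.Q, "q_p": fe.q_p, "tau2": re.tau2,
                    "pooled": len(studies) == 2}
        rows.append(row)
    return pd.DataFrame(rows)
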