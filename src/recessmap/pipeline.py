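"""End-to-end driver: simulate -> derive traits -> GRM/PCs -> association
(both genetic models) -> inflation -> ancestry frequencies -> manifest.

Every stage consumes a child seed spawned from the config seed, so a
rerun with the same config reproduces every stochastic output
bit-for-bit.  Stage outputs are written next to ``out_prefix``; failures
leave a ``.partial`` marker naming the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import admixture_em, estimate_component_eaf_table
from .assoc import (bonferroni_threshold, compute_grm, compute_pcs,
                    encode_genotype, genomic_inflation, lmm_scan,
                    logistic_assoc)
from .io import PipelineConfig, read_phenotypes, read_plink, write_phenotypes, write_plink
from .simulate import simulate_cohort
from .traits import derive_traits

logger = logging.getLogger("recessmap")

__all__ = ["run_pipeline"]


def _params_hash(config: PipelineConfig) -> str:
    params = {k: v for k, v in config.to_dict().items()
              if k not in ("out_prefix", "genotypes", "phenotypes")}
    blob = json.dumps(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    partial = prefix.with_suffix(".partial")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params_hash": _params_hash(config),
        "stages": [],
    }
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("simulate", "assoc", "ancestry"), ss.spawn(3))}

    def stage(name):
        logger.info("stage=%s seed=%s", name, config.seed)
        manifest["stages"].append(name)

    try:
        partial.write_text("running")
        stage("simulate")
        if config.genotypes is None:
            G, pheno, model = simulate_cohort(
                n=config.n, m=config.m, K=config.K,
                causal_freqs=(config.eaf_inuit, config.eaf_eu),
                or_effect=config.or_effect,
                baseline_risk=config.baseline_risk,
                divergence=config.divergence,
                missing_rate=config.missing_rate,
                seed=int(seeds["simulate"].generate_state(1)[0] % (2**31)),
            )
            write_plink(prefix, G)
            write_phenotypes(prefix.with_suffix(".pheno.tsv"), pheno)
        else:
            G = read_plink(config.genotypes)
            pheno = read_phenotypes(config.phenotypes)
            model = None

        stage("derive_traits")
        traits = derive_traits(pheno)
        write_phenotypes(prefix.with_suffix(".traits.tsv"), traits)

        stage("grm_pca")
        grm = compute_grm(G)
        pcs = compute_pcs(G, min(config.n_pcs, min(G.dosages.shape) - 1))
        pd.DataFrame(grm.matrix).to_csv(
            prefix.with_suffix(".grm.tsv"), sep="\t", header=False,
            index=False, float_format="%.8g")

        stage("assoc")
        status = pheno["status"].to_numpy(float)
        covars = np.column_stack([
            pheno["age"].to_numpy(float), pheno["sex"].to_numpy(float)])
        frames = []
        for gm in ("additive", "recessive"):
            scan = lmm_scan(status, G, covars=covars, K=grm, model=gm)
            ors = np.full(len(scan), np.nan)
            cov_or = np.column_stack([covars, pcs])
            for j in range(G.n_snps):
                x = encode_genotype(G.dosages[:, j], gm)
                res = logistic_assoc(status, x, covars=cov_or, model=gm)
                ors[j] = res.odds_ratio
            scan["or"] = ors
            scan["chr"] = G.chrom
            scan["pos"] = G.pos
            scan["effect_allele"] = G.effect_alleles
            frames.append(scan)
        assoc = pd.concat(frames, ignore_index=True)
        assoc = assoc[["snp_id", "chr", "pos", "effect_allele", "model",
                       "n_used", "n_hom", "beta", "se", "p", "or",
                       "variance_ratio"]]
        assoc.to_csv(prefix.with_suffix(".assoc.tsv"), sep="\t", index=False,
                     na_rep=".", float_format="%.8g")

        stage("inflation")
        pvals = assoc.loc[assoc["model"] == "recessive", "p"].dropna()
        lam = genomic_inflation(np.clip(pvals.to_numpy(), 1e-300, 1.0))
        manifest["genomic_inflation_recessive"] = lam
        manifest["bonferroni_threshold"] = bonferroni_threshold(G.n_snps)

        stage("ancestry_freq")
        if model is not None:
            Q = model.Q  # true simulated proportions are on disk for reruns
        else:
            Q = admixture_em(G, K=config.K,
                             seed=int(seeds["ancestry"].generate_state(1)[0] % (2**31))).Q
        table = estimate_component_eaf_table(
            G, Q, snp_ids=[str(G.snp_ids[0])], B=config.B,
            seed=int(seeds["ancestry"].generate_state(1)[0] % (2**31)))
        table.to_csv(prefix.with_suffix(".ancestry_freq.tsv"), sep="\t",
                     index=False, na_rep=".", float_format="%.8g")

        with open(prefix.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        partial.unlink(missing_ok=True)
        return manifest
    except Exception as exc:
        failing = manifest["stages"][-1] if manifest["stages"] else "init"
        partial.write_text(f"failed at stage {failing}: {exc}")
        logger.error("pipeline failed at stage %s: %s", failing, exc)
        raise
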