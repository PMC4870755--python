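"""End-to-end orchestration: simulate -> haplotype -> call -> stats.

A single PipelineConfig drives every stage; all randomness flows from its
seeds, so two runs with equal manifests produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import defaults, repro, simulate, variants
from .genome import (AnnotatedGenome, MthapError, write_annotation,
                     write_fasta, write_fastq, write_newick)
from .haplotyping import (assign_haplotypes, bootstrap_support,
                          find_distinguishing_sites, pairwise_distances)

log = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineConfig(BaseModel):
    """All pipeline parameters; thresholds default to the documented values."""

    out_dir: str = "mthap-out"
    reference_fasta: Optional[str] = None    # None -> build the synthetic one
    annotation_tsv: Optional[str] = None

    # simulation
    seed: int = 1
    individuals_per_haplotype: int = 1
    depth: float = 250.0
    read_length: int = 120
    error_rate: float = 0.0
    duplicate_fraction: float = 0.10

    # QC / alignment / calling
    min_read_length: int = 15
    trim_each_end: int = 1
    min_phred: float = 15.0
    mismatch_cost: float = 2.0
    indel_cost: float = 3.0
    min_identity: float = 0.80
    min_variant_reads: int = 50
    min_frequency: float = 0.03
    min_consensus_depth: int = 10

    # haplotyping
    haplotype_threshold: float = 4e-4
    n_bootstrap: int = 100

    # phenotypes / coupling
    delc_r2: float = 0.82

    @field_validator("depth", "read_length", "min_identity")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v

    def qc_params(self) -> variants.QCParams:
        return variants.QCParams(self.min_read_length, self.trim_each_end,
                                 self.min_phred)

    def align_params(self) -> variants.AlignParams:
        return variants.AlignParams(self.mismatch_cost, self.indel_cost,
                                    self.min_identity)

    def thresholds(self) -> variants.CallThresholds:
        return variants.CallThresholds(self.min_variant_reads,
                                       self.min_frequency, True,
                                       self.min_consensus_depth)

    def manifest(self) -> dict:
        blob = json.dumps(self.model_dump(), sort_keys=True)
        return {
            "version": __version__,
            "parameters": self.model_dump(),
            "parameter_hash": hashlib.sha256(blob.encode()).hexdigest(),
        }


def load_config(path) -> PipelineConfig:
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


# built-in heteroplasmy scheme for simulated individuals: the CYTB hotspot
# shared by every haplotype, the D-only CYTB deletion, and the two D-loop
# deletions near CSBII. Frequencies vary by individual via the seed.
def _heteroplasmy_spec(reference: AnnotatedGenome, hap: str, delc_level: float,
                       rng) -> simulate.HeteroplasmySpec:
    variants_ = [
        simulate.HetVariant(14230, reference.base(14230), "", "deletion",
                            float(rng.uniform(0.26, 0.30))),
        simulate.HetVariant(16383, reference.base(16383), "", "deletion",
                            float(delc_level)),
        simulate.HetVariant(16392, reference.base(16392), "", "deletion",
                            float(rng.uniform(0.04, 0.10))),
    ]
    if hap == "D":
        variants_.append(simulate.HetVariant(
            14237, reference.base(14237), "", "deletion",
            float(rng.uniform(0.26, 0.30))))
    return simulate.HeteroplasmySpec(variants_)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage over synthetic inputs and write the artifact directory."""
    import numpy as np

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- reference and haplotype consensuses -------------------------------
    reference = simulate.build_reference(config.seed)
    profiles = simulate.builtin_profiles()
    consensuses = {h: simulate.apply_profile(reference, p)
                   for h, p in profiles.items()}
    write_fasta(out / "reference.fasta", [(reference.name, reference.sequence)])
    write_annotation(out / "annotation.tsv", reference.features)
    write_fasta(out / "haplotypes.fasta",
                [(h, c.sequence) for h, c in sorted(consensuses.items())])

    sites, shared = find_distinguishing_sites(consensuses, reference)
    pd.DataFrame(
        [(s.position, s.unique_to, s.kind, ";".join(a for _, a in s.alleles))
         for s in sites],
        columns=["position", "unique_to", "kind", "alleles"],
    ).to_csv(out / "distinguishing_sites.csv", index=False)

    # --- phenotypes ---------------------------------------------------------
    pheno = simulate.simulate_phenotypes(simulate.PhenotypeSimParams(
        delc_r2=config.delc_r2, seed=config.seed))
    for name, df in pheno.items():
        df.to_csv(out / f"{name}.csv", index=False)

    # --- per-individual reads, haplotyping, variant calls ------------------
    d0, d1 = defaults.D_LOOP_SPAN
    dloop_seqs, dloop_labels = [], []
    calls_by_individual: dict[str, list[variants.VariantCall]] = {}
    truth_frames = []
    true_hap = {}

    for hap in sorted(consensuses):
        cons = consensuses[hap]
        pos_index = cons.position_index()
        for k in range(config.individuals_per_haplotype):
            ind = f"{hap}{k + 1}"
            true_hap[ind] = hap
            # D-loop sequence projected to reference coordinates
            dloop = "".join(
                cons.sequence[pos_index[p]] if p in pos_index else "-"
                for p in range(d0, d1 + 1))
            dloop_seqs.append(dloop)
            dloop_labels.append(ind)

            spec = _heteroplasmy_spec(reference, hap,
                                      rng.uniform(0.15, 0.28), rng)
            reads, truth = simulate.simulate_reads(
                cons, spec,
                simulate.ReadSimParams(
                    depth=config.depth, read_length=config.read_length,
                    error_rate=config.error_rate,
                    duplicate_fraction=config.duplicate_fraction,
                    seed=int(rng.integers(0, 2**31))))
            truth["individual"] = ind
            truth_frames.append(truth)
            calls, _, _ = variants.call_variants(
                reads, reference, config.qc_params(), config.align_params(),
                config.thresholds())
            calls_by_individual[ind] = calls

    pd.concat(truth_frames).to_csv(out / "truth.tsv", sep="\t", index=False)

    dm = pairwise_distances(dloop_seqs, dloop_labels)
    assignment = assign_haplotypes(dm, config.haplotype_threshold)
    tree, _ = bootstrap_support(dloop_seqs, dloop_labels,
                                n_replicates=config.n_bootstrap,
                                seed=config.seed)
    (out / "tree.nwk").write_text(write_newick(tree) + "\n")
    pd.DataFrame(sorted(assignment.assignments.items()),
                 columns=["individual", "haplotype"]
                 ).to_csv(out / "assignments.csv", index=False)

    labels = assignment.assignments
    if any(v == "unassigned" for v in labels.values()):
        raise MthapError("stage haplotyping: unassigned individuals present")

    classified = variants.classify_polymorphisms(calls_by_individual, labels)
    variants.annotate_polymorphisms(classified, reference)
    calls_df = pd.DataFrame([
        dict(CHROM=reference.name, POS=c.call.position, REF=c.call.ref,
             ALT=c.call.alt, KIND=c.call.kind, FREQ=round(c.call.frequency, 4),
             FWD=c.call.fwd_count, REV=c.call.rev_count, DEPTH=c.call.depth,
             CLASS=c.cls, FEATURE=c.feature, COMPLEX=c.complex,
             AA_CHANGE=c.aa_change or "", INDIVIDUAL=c.individual,
             HAPLOTYPE=c.haplotype, NAME=c.call.name)
        for c in classified])
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)

    het = [c.call for c in classified if c.cls == "heteroplasmic_variant"]
    variants.susceptibility_profile(het, reference).to_csv(
        out / "susceptibility.tsv", sep="\t", index=False)
    load = variants.variant_load(calls_by_individual, labels,
                                 frequency_floor=0.25)
    pd.DataFrame(sorted(load.items()), columns=["haplotype", "mean_variants"]
                 ).to_csv(out / "variant_load.csv", index=False)

    # --- phenotype statistics ----------------------------------------------
    summary = repro.summarize_phenotypes(pheno["sows"])
    summary.to_csv(out / "phenotype_summary.csv", index=False)

    ovaries = pheno["ovaries"]
    ratios = ovaries.groupby("haplotype").apply(
        lambda g: (g["bcb_pos"] / g["bcb_neg"]).mean(), include_groups=False)
    embryos = pheno["embryos"]
    by_hap = embryos.groupby("haplotype")
    stage_means = {
        hap: {
            "BCB_ratio": float(ratios[hap]),
            "maturation": float(g["matured"].mean()),
            "fertilization": float(g.loc[g["matured"], "fertilized"].mean()),
            "blastocyst": float(g.loc[g["fertilized"], "blastocyst"].mean()),
        }
        for hap, g in by_hap
    }
    litter_means = dict(zip(summary["haplotype"], summary["litter_mean"]))
    repro.efficiency_index(stage_means, litter_means).to_csv(
        out / "efficiency.csv", index=False)

    # correlation of 16383delC level with copy number (MII oocytes)
    oo = pheno["oocytes"]
    mii = oo[oo["stage"] == "MII"]
    r, r2, p = repro.correlate(mii["delc16383_level"], mii["copy_number"])
    (out / "correlations.json").write_text(json.dumps(
        {"delc16383_vs_copy_number": {"r": r, "r2": r2, "p": p}}, indent=2))

    (out / "manifest.json").write_text(
        json.dumps(config.manifest(), indent=2, sort_keys=True))
    return out
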