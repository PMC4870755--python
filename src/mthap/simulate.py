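"""Synthetic-data generators: reference genome, haplotype consensuses,
heteroplasmic read sets with a known truth table, phenotype tables, and qPCR
runs. Every generator is deterministic given its parameters and seed.

These generators define the study conditions the rest of the package is
exercised against: a 16,679 bp circular genome, five haplotypes differing at
28 documented sites, per-individual heteroplasmies at 3-49% frequency, deep
single-end amplicon reads, and phenotype tables with the documented group
structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import defaults
from .genome import AnnotatedGenome, Feature, MthapError, ReadRecord, revcomp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# profiles and consensuses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Polymorphism:
    """One nucleotide change relative to the reference.

    SNV: ref/alt are single bases at `position`. Deletion: ref is the deleted
    base at `position`, alt is "". Insertion: ref is "", alt is the base
    inserted immediately after `position`.
    """

    position: int
    ref: str
    alt: str
    kind: str  # SNV | insertion | deletion

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown change kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "SNV":
            return f"{self.position}{self.ref}>{self.alt}"
        if self.kind == "deletion":
            return f"{self.position}del{self.ref}"
        return f"{self.position}ins{self.alt}"


@dataclass
class HaplotypeProfile:
    """A named set of defining polymorphisms applied to the reference."""

    haplotype_id: str
    polymorphisms: list[Polymorphism]

    def __post_init__(self) -> None:
        positions = [p.position for p in self.polymorphisms]
        if len(positions) != len(set(positions)):
            raise ValueError(
                f"profile {self.haplotype_id}: duplicate positions in profile"
            )


def builtin_profiles(include_shared: bool = True) -> dict[str, HaplotypeProfile]:
    """The five built-in haplotype profiles.

    Each profile carries its haplotype-unique polymorphisms (28 sites across
    the five profiles) and, by default, the shared hypervariable D-loop sites
    carried by several haplotypes at once. Shared sites never count as
    distinguishing.
    """
    out = {}
    for hap, rows in defaults.HAPLOTYPE_PROFILES.items():
        poly = [Polymorphism(p, r, a, k) for (p, r, a, k) in rows]
        if include_shared:
            poly.extend(
                Polymorphism(p, r, a, "SNV")
                for (p, r, a, carriers) in defaults.SHARED_DLOOP_POLYMORPHISMS
                if hap in carriers)
        poly.sort(key=lambda p: p.position)
        out[hap] = HaplotypeProfile(hap, poly)
    return out


@dataclass
class HaplotypeConsensus:
    """A haplotype consensus sequence with its reference-coordinate projection.

    ``ref_map[i]`` is the 1-based reference position of consensus base ``i``,
    or None for an inserted base. Reference positions absent from the map were
    deleted.
    """

    haplotype_id: str
    sequence: str
    ref_map: list[Optional[int]]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.ref_map):
            raise ValueError("sequence and ref_map lengths differ")

    def position_index(self) -> dict[int, int]:
        """Map reference position -> 0-based consensus index."""
        return {p: i for i, p in enumerate(self.ref_map) if p is not None}


def apply_profile(reference: AnnotatedGenome,
                  profile: HaplotypeProfile) -> HaplotypeConsensus:
    """Apply a profile to the reference, verifying every ref allele."""
    mismatches = [
        p for p in profile.polymorphisms
        if p.kind != "insertion" and reference.base(p.position) != p.ref
    ]
    if mismatches:
        sites = ", ".join(f"{p.position} (genome {reference.base(p.position)}, "
                          f"profile {p.ref})" for p in mismatches)
        raise MthapError(f"profile {profile.haplotype_id}: reference allele "
                         f"mismatch at {sites}")

    by_pos = {p.position: p for p in profile.polymorphisms}
    seq: list[str] = []
    ref_map: list[Optional[int]] = []
    for pos in range(1, reference.length + 1):
        change = by_pos.get(pos)
        if change is None or change.kind == "insertion":
            seq.append(reference.base(pos))
            ref_map.append(pos)
            if change is not None:  # insertion anchored after pos
                for b in change.alt:
                    seq.append(b)
                    ref_map.append(None)
        elif change.kind == "SNV":
            seq.append(change.alt)
            ref_map.append(pos)
        # deletion: emit nothing for this position
    return HaplotypeConsensus(profile.haplotype_id, "".join(seq), ref_map)


def diff_against_reference(consensus: HaplotypeConsensus,
                           reference: AnnotatedGenome) -> list[Polymorphism]:
    """Reverse-diff a consensus against the reference; inverse of apply_profile."""
    changes: list[Polymorphism] = []
    seen = set()
    last_ref = 0
    i = 0
    n = len(consensus.sequence)
    while i < n:
        pos = consensus.ref_map[i]
        if pos is None:
            inserted = []
            while i < n and consensus.ref_map[i] is None:
                inserted.append(consensus.sequence[i])
                i += 1
            changes.append(Polymorphism(last_ref, "", "".join(inserted),
                                        "insertion"))
            continue
        for missing in range(last_ref + 1, pos):
            changes.append(Polymorphism(missing, reference.base(missing), "",
                                        "deletion"))
        base = consensus.sequence[i]
        if base != reference.base(pos):
            changes.append(Polymorphism(pos, reference.base(pos), base, "SNV"))
        seen.add(pos)
        last_ref = pos
        i += 1
    for missing in range(last_ref + 1, reference.length + 1):
        changes.append(Polymorphism(missing, reference.base(missing), "",
                                    "deletion"))
    changes.sort(key=lambda p: p.position)
    return changes


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSpec:
    """Feature layout plus base constraints for the synthetic backbone."""

    features: list[Feature]
    base_constraints: dict[int, str] = field(default_factory=dict)

    def validate(self, length: int) -> None:
        for f in self.features:
            if f.end > length:
                raise MthapError(f"feature {f.name} extends past {length}")
            if f.kind == "CDS" and (f.length(length) - f.codon_start_offset) % 3:
                raise MthapError(f"CDS {f.name}: frame incompatible with span")
        for pos, base in self.base_constraints.items():
            if not 1 <= pos <= length:
                raise MthapError(f"base constraint at {pos} outside genome")
            if base not in "ACGT":
                raise MthapError(f"base constraint at {pos}: invalid base {base}")


def default_annotation_spec() -> AnnotationSpec:
    return AnnotationSpec(defaults.default_features(),
                          dict(defaults.BASE_CONSTRAINTS))


def build_reference(seed: int,
                    length: int = defaults.PIG_MTDNA_LENGTH,
                    annotation_spec: Optional[AnnotationSpec] = None,
                    gc: float = 0.40) -> AnnotatedGenome:
    """Random circular reference genome with the given annotation.

    Deterministic for a given seed; GC content ~= ``gc``. Base constraints in
    the annotation spec are applied after the random fill so that documented
    reference alleles and codon contexts hold.
    """
    if annotation_spec is None:
        annotation_spec = default_annotation_spec()
    annotation_spec.validate(length)
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    seq = bytearray(bases.tobytes())
    for pos, base in annotation_spec.base_constraints.items():
        seq[pos - 1] = ord(base)
    return AnnotatedGenome(
        name="synthetic-pig-mtDNA",
        sequence=seq.decode(),
        circular=True,
        features=list(annotation_spec.features),
        accession=None,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HetVariant:
    position: int          # reference coordinate
    ref: str
    alt: str
    kind: str              # SNV | insertion | deletion
    frequency: float
    strand_restrict: Optional[str] = None  # force variant reads to one strand

    def __post_init__(self) -> None:
        if not 0 < self.frequency < 1:
            raise ValueError(f"target frequency must be in (0,1), "
                             f"got {self.frequency}")

    @property
    def name(self) -> str:
        if self.kind == "SNV":
            return f"{self.position}{self.ref}>{self.alt}"
        if self.kind == "deletion":
            return f"{self.position}del{self.ref}"
        return f"{self.position}ins{self.alt}"


@dataclass
class HeteroplasmySpec:
    """Per-individual heteroplasmic variants with target frequencies."""

    variants: list[HetVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(v.frequency for v in self.variants)
        if total >= 1.0:
            raise ValueError("summed variant frequencies must stay below 1 "
                             "(each molecule carries at most one variant)")


@dataclass
class ReadSimParams:
    depth: float = 500.0          # scaled-down default; study depth ~3395x
    read_length: int = 100
    read_length_sd: float = 12.0  # amplicon reads vary in length
    error_rate: float = 0.0
    duplicate_fraction: float = 0.10
    strand_balance: float = 0.5
    base_quality: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.read_length_sd < 0:
            raise ValueError("read_length_sd must be >= 0")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0,1)")
        if not 0 < self.strand_balance < 1:
            raise ValueError("strand_balance must be in (0,1)")


def simulate_reads(
    individual: Union[AnnotatedGenome, HaplotypeConsensus, str],
    spec: HeteroplasmySpec,
    params: ReadSimParams,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw single-end reads from a heteroplasmic molecule population.

    Each read is drawn from either the consensus molecule or one of the
    variant molecules according to the target frequencies (each variant
    molecule carries exactly one variant). Duplicates are exact copies of an
    earlier read; both strands are emitted per ``strand_balance``. Reads never
    span the circular origin.

    Returns the reads and the truth table (position, ref, alt, kind,
    frequency) that serves as the evaluation oracle downstream.
    """
    if isinstance(individual, AnnotatedGenome):
        seq = individual.sequence
        pos_index = {p: p - 1 for p in range(1, individual.length + 1)}
    elif isinstance(individual, HaplotypeConsensus):
        seq = individual.sequence
        pos_index = individual.position_index()
    else:
        seq = str(individual).upper()
        pos_index = {p: p - 1 for p in range(1, len(seq) + 1)}

    # validate the spec against the molecule the reads are drawn from
    for v in spec.variants:
        if v.position not in pos_index and v.kind != "insertion":
            raise MthapError(f"variant position {v.position} not present in "
                             "the individual genome")
        if v.kind in ("SNV", "deletion"):
            have = seq[pos_index[v.position]]
            if have != v.ref:
                raise MthapError(f"variant at {v.position}: genome has {have}, "
                                 f"spec says ref {v.ref}")

    L = len(seq)
    rl = min(params.read_length, L)
    n_total = int(round(params.depth * L / rl))
    n_dup = int(round(params.duplicate_fraction * n_total))
    n_orig = n_total - n_dup

    for v in spec.variants:
        if params.depth * v.frequency < 50:
            log.warning(
                "variant %s at frequency %.3f: expected support %.0f reads "
                "is below the 50-read calling floor at depth %.0fx",
                v.name, v.frequency, params.depth * v.frequency, params.depth)

    rng = np.random.default_rng(params.seed)
    if params.read_length_sd > 0 and rl < L:
        lengths = np.clip(
            np.rint(rng.normal(rl, params.read_length_sd, size=n_orig)),
            15, L).astype(int)
    else:
        lengths = np.full(n_orig, rl)
    starts = (rng.random(n_orig) * (L - lengths + 1)).astype(int)
    fwd = rng.random(n_orig) < params.strand_balance
    freqs = np.array([v.frequency for v in spec.variants])
    if len(freqs):
        probs = np.concatenate([freqs, [1.0 - freqs.sum()]])
        molecule = rng.choice(len(freqs) + 1, size=n_orig, p=probs)
    else:
        molecule = np.full(n_orig, 0)
    for vi, v in enumerate(spec.variants):
        if v.strand_restrict is not None:
            fwd[molecule == vi] = v.strand_restrict == "+"

    reads: list[ReadRecord] = []
    for i in range(n_orig):
        s = int(starts[i])
        bases = seq[s : s + int(lengths[i])]
        if len(freqs) and molecule[i] < len(freqs):
            v = spec.variants[molecule[i]]
            idx = pos_index[v.position] - s
            if 0 <= idx < len(bases):
                if v.kind == "SNV":
                    bases = bases[:idx] + v.alt + bases[idx + 1:]
                elif v.kind == "deletion":
                    bases = bases[:idx] + bases[idx + 1:]
                else:  # insertion after the anchor base
                    bases = bases[: idx + 1] + v.alt + bases[idx + 1:]
        if params.error_rate > 0:
            n_err = rng.binomial(len(bases), params.error_rate)
            if n_err:
                barr = bytearray(bases.encode())
                for j in rng.choice(len(barr), size=n_err, replace=False):
                    choices = [b for b in b"ACGT" if b != barr[j]]
                    barr[j] = choices[rng.integers(0, 3)]
                bases = barr.decode()
        if not fwd[i]:
            bases = revcomp(bases)
        quals = [params.base_quality] * len(bases)
        strand = "+" if fwd[i] else "-"
        reads.append(ReadRecord(f"r{i}/{strand}", bases, quals))

    if n_dup:
        picks = rng.integers(0, n_orig, size=n_dup)
        for j, k in enumerate(picks):
            src = reads[int(k)]
            reads.append(ReadRecord(f"{src.id}_dup{j}", src.bases,
                                    list(src.quals)))
    else:
        picks = np.empty(0, dtype=int)

    # truth table: the evaluation oracle downstream. `frequency` is the
    # realized variant fraction among the unique reads overlapping the site
    # (duplicates excluded, as deduplication removes them by design);
    # `target_frequency` is the requested population level.
    rows = []
    for vi, v in enumerate(spec.variants):
        idx = pos_index.get(v.position)
        if idx is None:
            rows.append((v.position, v.ref, v.alt, v.kind, v.frequency,
                         v.frequency, v.name))
            continue
        covers = (starts <= idx) & (starts + lengths > idx)
        n_cover = int(covers.sum())
        n_alt = int((covers & (molecule == vi)).sum())
        realized = n_alt / n_cover if n_cover else 0.0
        rows.append((v.position, v.ref, v.alt, v.kind, realized,
                     v.frequency, v.name))
    del picks
    truth = pd.DataFrame(
        rows, columns=["position", "ref", "alt", "kind", "frequency",
                       "target_frequency", "name"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSimParams:
    haplotype_params: dict[str, dict] = field(
        default_factory=lambda: {h: dict(v)
                                 for h, v in defaults.PHENOTYPE_DEFAULTS.items()})
    n_ovaries: int = 12
    n_cocs: int = 150
    n_oocytes: int = 20
    n_blastocysts: int = 10
    delc_r2: float = 0.82      # coupling between 16383delC level and copies
    delc_base: float = 0.30
    delc_scale: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.delc_r2 <= 1:
            raise ValueError("delc_r2 must be in [0,1]")
        for hap, p in self.haplotype_params.items():
            for key in ("maturation_p", "fertilization_p", "blastocyst_p"):
                if not 0 <= p[key] <= 1:
                    raise ValueError(f"{hap}: {key} outside [0,1]")


def couple_delc_to_copies(copies: Sequence[float], r2: float, seed: int,
                          base: float = 0.30, scale: float = 0.08) -> np.ndarray:
    """Variant levels linearly coupled to copy number with configured R^2.

    The noise term is calibrated against the realized spread of the supplied
    copy numbers so the configured signal fraction holds for the cohort being
    generated. Levels are clipped to (0.01, 0.95).
    """
    x = np.asarray(copies, dtype=float)
    if len(x) < 2 or np.std(x) == 0:
        raise MthapError("need >=2 distinct copy numbers for coupling")
    rng = np.random.default_rng(seed)
    xz = (x - x.mean()) / x.std()
    if r2 >= 1.0:
        signal = xz
        noise = np.zeros_like(xz)
    else:
        e = rng.standard_normal(len(x))
        if np.std(e) == 0:
            e = np.linspace(-1, 1, len(x))
        ez = (e - e.mean()) / e.std()
        signal = math.sqrt(r2) * xz
        noise = math.sqrt(1 - r2) * ez
    levels = base + scale * (signal + noise)
    return np.clip(levels, 0.01, 0.95)


def _rounded_normal(rng, mean, sd, size, low=0):
    vals = np.rint(rng.normal(mean, sd, size=size)).astype(int)
    return np.maximum(vals, low)


def simulate_phenotypes(params: PhenotypeSimParams) -> dict[str, pd.DataFrame]:
    """Phenotype tables with the documented per-haplotype group structure.

    Returns dataframes: sows (one row per parity), ovaries (BCB counts),
    oocytes (stage + copy number + 16383delC level), embryos (per-COC
    maturation/fertilization/blastocyst outcomes).
    """
    rng = np.random.default_rng(params.seed)
    sow_rows, ovary_rows, oocyte_rows, embryo_rows = [], [], [], []

    for hap, p in sorted(params.haplotype_params.items()):
        litter_sd = p["litter_sem"] * math.sqrt(p["n_litters"])
        still_sd = p["stillborn_sem"] * math.sqrt(p["n_litters"])
        # distribute litters across sows (3-10 parities per sow in the study)
        per_sow = np.full(p["n_sows"], p["n_litters"] // p["n_sows"])
        per_sow[: p["n_litters"] % p["n_sows"]] += 1
        litters = _rounded_normal(rng, p["litter_mean"], litter_sd,
                                  p["n_litters"])
        stills = _rounded_normal(rng, p["stillborn_mean"], still_sd,
                                 p["n_litters"])
        stills = np.minimum(stills, litters)
        k = 0
        for s in range(p["n_sows"]):
            for parity in range(1, int(per_sow[s]) + 1):
                sow_rows.append((f"{hap}{s:03d}", hap, parity,
                                 int(litters[k]), int(stills[k])))
                k += 1

        ratio_sd = p["bcb_ratio_sem"] * math.sqrt(params.n_ovaries)
        for o in range(params.n_ovaries):
            neg = int(rng.poisson(8)) + 2
            ratio = max(0.1, rng.normal(p["bcb_ratio_mean"], ratio_sd))
            pos = max(0, int(round(ratio * neg)))
            ovary_rows.append((f"{hap}-ov{o:02d}", hap, pos, neg))

        # copy numbers: lognormal with the documented group mean / SEM
        for stage, mean_scale, n in (
            ("MII", 1.0, params.n_oocytes),
            ("blastocyst", p["fold_blast"], params.n_blastocysts),
        ):
            m = p["copies_mean"] * mean_scale
            sd = p["copies_sem"] * math.sqrt(params.n_oocytes) * mean_scale
            sigma2 = math.log(1 + (sd / m) ** 2)
            mu = math.log(m) - sigma2 / 2
            copies = rng.lognormal(mu, math.sqrt(sigma2), size=n)
            for i, c in enumerate(copies):
                oocyte_rows.append((f"{hap}-{stage}-{i:02d}", hap, stage,
                                    float(c)))

        mat = rng.random(params.n_cocs) < p["maturation_p"]
        fert = mat & (rng.random(params.n_cocs) < p["fertilization_p"])
        blast = fert & (rng.random(params.n_cocs) < p["blastocyst_p"])
        for i in range(params.n_cocs):
            embryo_rows.append((f"{hap}-coc{i:03d}", hap, bool(mat[i]),
                                bool(fert[i]), bool(blast[i])))

    oocytes = pd.DataFrame(
        oocyte_rows, columns=["oocyte_id", "haplotype", "stage", "copy_number"])
    mii = oocytes["stage"] == "MII"
    levels = np.full(len(oocytes), np.nan)
    levels[mii.to_numpy()] = couple_delc_to_copies(
        oocytes.loc[mii, "copy_number"].to_numpy(),
        params.delc_r2, int(rng.integers(0, 2**31)),
        params.delc_base, params.delc_scale)
    oocytes["delc16383_level"] = levels

    return {
        "sows": pd.DataFrame(
            sow_rows, columns=["sow_id", "haplotype", "parity", "litter_size",
                               "stillborn"]),
        "ovaries": pd.DataFrame(
            ovary_rows, columns=["ovary_id", "haplotype", "bcb_pos", "bcb_neg"]),
        "oocytes": oocytes,
        "embryos": pd.DataFrame(
            embryo_rows, columns=["coc_id", "haplotype", "matured",
                                  "fertilized", "blastocyst"]),
    }


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_copies: Sequence[float],
    curve_slope: float = defaults.QPCR_SLOPE,
    curve_intercept: float = defaults.QPCR_INTERCEPT,
    noise_sd: float = 0.0,
    seed: int = 0,
    length_bp: int = defaults.PIG_MTDNA_LENGTH,
    dilution_factor: float = defaults.OOCYTE_DILUTION_FACTOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct values for unknowns plus the 9-point 10-fold standard series.

    Ct = intercept + slope * log10(template ng) + Gaussian noise. Standards
    run 1 ng/uL down to 1e-8 ng/uL. Unknown template amounts derive from the
    per-sample copy number divided by the dilution factor (2 uL of 50 uL per
    reaction) and converted at 660 g/mol/bp.
    """
    if curve_slope >= 0:
        raise MthapError("standard-curve slope must be negative")
    copies = np.asarray(true_copies, dtype=float)
    if np.any(copies <= 0):
        raise MthapError("copy numbers must be positive")
    rng = np.random.default_rng(seed)

    amounts = 10.0 ** -np.arange(9)  # 1 .. 1e-8 ng/uL
    ct_std = (curve_intercept + curve_slope * np.log10(amounts)
              + rng.normal(0, noise_sd, size=len(amounts)))
    standards = pd.DataFrame({"amount_ng": amounts, "ct": ct_std})

    ng_per_copy = length_bp * defaults.DNA_GRAMS_PER_MOL_BP * 1e9 / defaults.AVOGADRO
    amount_ng = copies / dilution_factor * ng_per_copy
    ct = (curve_intercept + curve_slope * np.log10(amount_ng)
          + rng.normal(0, noise_sd, size=len(copies)))
    unknowns = pd.DataFrame({
        "sample": [f"s{i}" for i in range(len(copies))],
        "true_copies": copies,
        "ct": ct,
    })
    return unknowns, standards
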