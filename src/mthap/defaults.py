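"""Built-in study conditions: the pig-like mitochondrial annotation, the five
haplotype-defining polymorphism profiles, and phenotype generator defaults.

The reference genome produced from this layout is synthetic: a random backbone
constrained so that every profile site carries the documented reference allele,
every site falls inside its documented gene region, and the annotated codons
carry the documented amino acids. The feature layout follows the gene order of
the pig mitochondrial genome (16,679 bp).
"""

from __future__ import annotations

from .genome import Feature

PIG_MTDNA_LENGTH = 16679

# name, kind, start, end, strand, complex, codon_start_offset
_LAYOUT = [
    ("tRNA-Phe", "tRNA", 1, 69, "+", None),
    ("12S-rRNA", "rRNA", 70, 1025, "+", None),
    ("tRNA-Val", "tRNA", 1026, 1092, "+", None),
    ("16S-rRNA", "rRNA", 1093, 2763, "+", None),
    ("tRNA-Leu", "tRNA", 2764, 2838, "+", None),
    ("NADH1", "CDS", 2839, 3795, "+", "I"),
    ("tRNA-Ile", "tRNA", 3796, 3850, "+", None),
    ("tRNA-Gln", "tRNA", 3851, 3909, "-", None),
    ("NADH2", "CDS", 3910, 4959, "+", "I"),
    ("tRNA-Trp", "tRNA", 4960, 5028, "+", None),
    ("tRNA-Ala", "tRNA", 5029, 5096, "-", None),
    ("tRNA-Asn", "tRNA", 5097, 5170, "-", None),
    ("tRNA-Cys", "tRNA", 5171, 5236, "-", None),
    ("tRNA-Tyr", "tRNA", 5237, 5303, "-", None),
    ("COI", "CDS", 5304, 6848, "+", "IV"),
    # 6849..6919 intergenic (site 6879 has no overlapping gene)
    ("tRNA-Asp", "tRNA", 6920, 6988, "+", None),
    ("COII", "CDS", 6989, 7672, "+", "IV"),
    ("tRNA-Lys", "tRNA", 7673, 7736, "+", None),
    ("ATPase8", "CDS", 7737, 7952, "+", "V"),   # overlaps ATPase6 by 10 bp
    ("ATPase6", "CDS", 7943, 8623, "+", "V"),
    ("COIII", "CDS", 8624, 9409, "+", "IV"),
    ("tRNA-Gly", "tRNA", 9410, 9475, "+", None),
    ("NADH3", "CDS", 9476, 9820, "+", "I"),
    ("tRNA-Arg", "tRNA", 9821, 9887, "+", None),
    ("NADH4L", "CDS", 9888, 10184, "+", "I"),
    ("NADH4", "CDS", 10185, 11561, "+", "I"),
    ("tRNA-His", "tRNA", 11562, 11630, "+", None),
    ("tRNA-Ser", "tRNA", 11631, 11689, "+", None),
    ("tRNA-Leu2", "tRNA", 11690, 11757, "+", None),
    ("NADH5", "CDS", 11758, 13560, "+", "I"),
    ("NADH6", "CDS", 13562, 14089, "-", "I"),
    ("tRNA-Glu", "tRNA", 14090, 14157, "-", None),
    ("CYTB", "CDS", 14158, 15297, "+", "III"),
    ("tRNA-Thr", "tRNA", 15298, 15364, "+", None),
    ("tRNA-Pro", "tRNA", 15365, 15430, "-", None),
    ("D-loop", "control", 15431, 16679, "+", None),
    ("CSBII", "motif", 16360, 16400, "+", None),  # inside the D-loop
]


def default_features() -> list[Feature]:
    return [
        Feature(name=n, kind=k, start=s, end=e, strand=st, complex=c)
        for (n, k, s, e, st, c) in _LAYOUT
    ]


# Reference-allele and codon-context constraints for the synthetic backbone.
# Codon contexts pin the amino acids documented for the annotated changes:
#   4897 ATT(Ile330)   9758 CTT(Leu95)   13423-25 ATT(Ile556)
#   13528-30 TTT(Phe591, printed reversed as Ser591Phe)
#   8114-16 ATA (Met in the mito code; printed Ile58Met is a standard-code call)
#   13898-900 CAT -> coding ATG on the minus strand (Met64)
BASE_CONSTRAINTS: dict[int, str] = {
    2309: "A",
    2312: "C",
    3060: "C",
    4179: "T",
    4897: "A", 4898: "T", 4899: "T",
    5585: "G",
    6053: "C",
    6212: "C",
    6359: "G",
    6879: "G",
    7430: "A",
    8114: "A", 8115: "T", 8116: "A",
    9758: "C", 9759: "T", 9760: "T",
    10283: "T",
    10629: "C",
    12216: "G",
    13423: "A", 13424: "T", 13425: "T",
    13528: "T", 13529: "T", 13530: "T",
    13898: "C", 13899: "A", 13900: "T",
    14378: "C",
    14594: "G",
    15212: "C",
    15615: "C",
    15675: "T",
    15758: "T",
    15840: "T",
    15936: "A",
    16127: "G",
    # heteroplasmy hotspots (CYTB deletions; D-loop/CSBII deletions)
    14230: "C",
    14237: "A",
    16383: "C",
    16392: "T",
}

# G-rich CSBII context around the 16383delC site (G-quadruplex-forming motif).
for _p in range(16375, 16383):
    BASE_CONSTRAINTS[_p] = "G"
for _p in range(16384, 16392):
    BASE_CONSTRAINTS[_p] = "G"

# The 28 haplotype-defining polymorphisms: (position, ref, alt, kind).
# Insertions are anchored after `position` (ref = ""); unique-site counts are
# A=4, B=3, C=13, D=5, E=3, and every haplotype carries >=1 D-loop site.
HAPLOTYPE_PROFILES: dict[str, list[tuple[int, str, str, str]]] = {
    "A": [
        (2309, "", "T", "insertion"),     # 2309 insT, 16S rRNA
        (6879, "G", "A", "SNV"),          # intergenic
        (8116, "A", "G", "SNV"),          # ATPase6 codon 58
        (15615, "C", "T", "SNV"),         # D-loop
    ],
    "B": [
        (2312, "C", "T", "SNV"),          # 16S rRNA
        (9758, "C", "A", "SNV"),          # NADH3 Leu95Ile
        (15675, "T", "C", "SNV"),         # D-loop
    ],
    "C": [
        (3060, "C", "T", "SNV"),          # NADH1
        (4179, "T", "C", "SNV"),          # NADH2
        (5585, "G", "A", "SNV"),          # COI
        (6053, "C", "T", "SNV"),          # COI
        (6212, "C", "T", "SNV"),          # COI
        (6359, "G", "A", "SNV"),          # COI
        (7430, "A", "G", "SNV"),          # COII
        (10283, "T", "C", "SNV"),         # NADH4
        (10629, "C", "T", "SNV"),         # NADH4
        (12216, "G", "C", "SNV"),         # NADH5
        (13898, "C", "T", "SNV"),         # NADH6 codon 64
        (14378, "C", "T", "SNV"),         # CYTB
        (15758, "T", "C", "SNV"),         # D-loop
    ],
    "D": [
        (4897, "A", "G", "SNV"),          # NADH2 Ile330Val
        (13424, "T", "C", "SNV"),         # NADH5 Ile556Thr
        (14594, "G", "A", "SNV"),         # CYTB
        (15212, "C", "T", "SNV"),         # CYTB
        (15840, "T", "C", "SNV"),         # D-loop
    ],
    "E": [
        (13529, "T", "C", "SNV"),         # NADH5 codon 591 (printed Ser591Phe)
        (15936, "A", "G", "SNV"),         # D-loop
        (16127, "G", "A", "SNV"),         # D-loop
    ],
}

D_LOOP_SPAN = (15431, 16679)

# Shared D-loop polymorphisms: hypervariable-region sites carried by four of
# the five haplotypes (the remaining lineage retains the ancestral base).
# They separate every haplotype pair by >= 12 extra D-loop sites, as the
# hypervariable segments do in real maternal lineages, without adding any
# haplotype-unique (distinguishing) site. Tuples: (position, ref, alt,
# carriers).
SHARED_DLOOP_POLYMORPHISMS: list[tuple[int, str, str, tuple[str, ...]]] = []
_shared_pos = 15440
for _absent in "ABCDE":
    _carriers = tuple(h for h in "ABCDE" if h != _absent)
    for _ in range(6):
        SHARED_DLOOP_POLYMORPHISMS.append((_shared_pos, "A", "G", _carriers))
        _shared_pos += 4
for _p, _r, _a, _c in SHARED_DLOOP_POLYMORPHISMS:
    BASE_CONSTRAINTS[_p] = _r

# ---------------------------------------------------------------------------
# phenotype defaults (per haplotype)
# ---------------------------------------------------------------------------
# Litter data: printed group means/SEM and group sizes. Stage probabilities
# back out of the efficiency indices (index x mean litter size). Copy-number
# means for B, D, E are printed; A and C are mid-range defaults. Fold changes
# for B, C, D printed; A and E default to 3.0.
PHENOTYPE_DEFAULTS: dict[str, dict] = {
    "A": dict(n_sows=30, n_litters=164, litter_mean=10.74, litter_sem=0.28,
              stillborn_mean=0.89, stillborn_sem=0.11,
              bcb_ratio_mean=2.93, bcb_ratio_sem=0.43,
              maturation_p=0.78, fertilization_p=0.81, blastocyst_p=0.20,
              copies_mean=450_000.0, copies_sem=60_000.0, fold_blast=3.0),
    "B": dict(n_sows=15, n_litters=78, litter_mean=11.12, litter_sem=0.41,
              stillborn_mean=0.97, stillborn_sem=0.16,
              bcb_ratio_mean=3.10, bcb_ratio_sem=0.45,
              maturation_p=0.76, fertilization_p=0.83, blastocyst_p=0.18,
              copies_mean=295_671.0, copies_sem=45_319.0, fold_blast=6.4),
    "C": dict(n_sows=19, n_litters=120, litter_mean=12.38, litter_sem=0.34,
              stillborn_mean=1.07, stillborn_sem=0.15,
              bcb_ratio_mean=4.09, bcb_ratio_sem=0.81,
              maturation_p=0.66, fertilization_p=0.71, blastocyst_p=0.17,
              copies_mean=500_000.0, copies_sem=70_000.0, fold_blast=2.5),
    "D": dict(n_sows=16, n_litters=101, litter_mean=11.96, litter_sem=0.45,
              stillborn_mean=1.07, stillborn_sem=0.16,
              bcb_ratio_mean=2.28, bcb_ratio_sem=0.53,
              maturation_p=0.72, fertilization_p=0.81, blastocyst_p=0.14,
              copies_mean=699_867.0, copies_sem=82_850.0, fold_blast=2.2),
    "E": dict(n_sows=14, n_litters=79, litter_mean=12.42, litter_sem=0.40,
              stillborn_mean=0.85, stillborn_sem=0.15,
              bcb_ratio_mean=2.53, bcb_ratio_sem=0.58,
              maturation_p=0.76, fertilization_p=0.85, blastocyst_p=0.20,
              copies_mean=410_301.0, copies_sem=96_392.0, fold_blast=3.0),
}

#: qPCR defaults: a perfectly efficient assay has slope -log2(10) = -3.3219.
QPCR_SLOPE = -3.3219
QPCR_INTERCEPT = 18.0
DNA_GRAMS_PER_MOL_BP = 660.0
AVOGADRO = 6.022e23
OOCYTE_DILUTION_FACTOR = 25.0  # 50 uL sample, 2 uL per reaction
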