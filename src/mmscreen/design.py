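"""Mismatch-CRISPRi guide series, control-guide screening and library
bottlenecking.

Knockdown strength is titrated by eroding guide-target complementarity one
base at a time: the first series member mutates the 5'-most base of the
20-nt targeting sequence, and each subsequent member additionally mutates
the base just 3' of the previous mutation, up to 10 consecutive mismatches
(11 guides per PAM site including the perfect-match guide).  Control guides
must share less than 8 bp of complementarity with any reference site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SgRNADesign",
    "CloneAssignment",
    "BottleneckStats",
    "TRANSVERSION_MAP",
    "mismatch_series",
    "control_guide_check",
    "longest_match_run",
    "simulate_bottleneck",
    "write_guide_table",
    "read_guide_table",
]

TRANSVERSION_MAP = {"A": "C", "C": "A", "G": "T", "T": "G"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
GUIDE_LENGTH = 20


def _validate_seq(seq: str, length: int | None = GUIDE_LENGTH) -> str:
    seq = seq.upper()
    if length is not None and len(seq) != length:
        raise ValueError(f"expected a {length}-nt sequence, got {len(seq)} nt")
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGT characters: {seq}")
    return seq


@dataclass(frozen=True)
class SgRNADesign:
    """One guide in a mismatch series."""

    gene: str
    pam_site: str
    targeting_seq: str
    n_mismatches: int

    def __post_init__(self) -> None:
        _validate_seq(self.targeting_seq)
        if not 0 <= self.n_mismatches <= 10:
            raise ValueError("n_mismatches must be in [0, 10]")


def mismatch_series(
    target: str,
    gene: str = "",
    pam_site: str = "",
    substitution_rule: dict[str, str] | None = None,
) -> list[SgRNADesign]:
    """Generate the 11-member consecutive-mismatch guide series for one target.

    Element 0 is the perfect-match guide; element i carries mismatches at
    exactly the i 5'-most positions.  The substituted base at each position
    is given by ``substitution_rule`` (default: transversions A<->C, G<->T),
    so the rule is deterministic and re-running reproduces the series.
    """
    target = _validate_seq(target)
    rule = substitution_rule or TRANSVERSION_MAP
    designs = [SgRNADesign(gene, pam_site, target, 0)]
    seq = list(target)
    for i in range(10):
        seq[i] = rule[target[i]]
        designs.append(SgRNADesign(gene, pam_site, "".join(seq), i + 1))
    return designs


def longest_match_run(candidate: str, reference: str) -> int:
    """Length of the longest exact substring of ``candidate`` present in ``reference``."""
    n = len(candidate)
    # n is 20: scanning windows longest-first is exact and cheap
    for k in range(n, 0, -1):
        for start in range(n - k + 1):
            if candidate[start : start + k] in reference:
                return k
    return 0


def control_guide_check(
    candidate: str,
    reference_seqs: list[str],
    max_complementarity: int = 7,
) -> bool:
    """Pass iff no window of the candidate or its reverse complement matches
    any reference with a run of ``max_complementarity + 1`` (default 8) or more."""
    candidate = _validate_seq(candidate)
    if not reference_seqs:
        raise ValueError("reference sequence set is empty")
    rc = candidate.translate(_COMPLEMENT)[::-1]
    for ref in reference_seqs:
        ref = ref.upper()
        for probe in (candidate, rc):
            if longest_match_run(probe, ref) > max_complementarity:
                return False
    return True


@dataclass
class BottleneckStats:
    mean_barcodes_per_variant: float
    median_barcodes_per_variant: float
    fraction_zero_barcode_variants: float
    counts: np.ndarray = field(repr=False)


@dataclass
class CloneAssignment:
    """barcode id -> (sgRNA index, 20-mer UMI) lookup built by bottlenecking."""

    table: pd.DataFrame  # columns: barcode_id, sgrna_id, umi
    stats: BottleneckStats

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", dtype={"umi": str})


def simulate_bottleneck(
    n_variants: int,
    n_clones: int,
    seed: int | np.random.Generator | None = None,
    umi_length: int = 20,
) -> CloneAssignment:
    """Bottleneck a combinatorial barcode-by-guide pool to ``n_clones`` clones.

    Each clone receives a unique barcode id, an sgRNA drawn uniformly at
    random, and a random UMI.  Barcode multiplicity per variant is then
    Binomial(n_clones, 1/n_variants), approximately Poisson at screen scale.
    """
    if n_variants < 1 or n_clones < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    sgrna_ids = rng.integers(0, n_variants, size=n_clones)
    nucs = np.array(list("ACGT"))
    umis = ["".join(nucs[rng.integers(0, 4, size=umi_length)]) for _ in range(n_clones)]
    table = pd.DataFrame(
        {"barcode_id": np.arange(n_clones), "sgrna_id": sgrna_ids, "umi": umis}
    )
    counts = np.bincount(sgrna_ids, minlength=n_variants)
    stats = BottleneckStats(
        mean_barcodes_per_variant=float(counts.mean()),
        median_barcodes_per_variant=float(np.median(counts)),
        fraction_zero_barcode_variants=float(np.mean(counts == 0)),
        counts=counts,
    )
    return CloneAssignment(table=table, stats=stats)


def write_guide_table(designs: list[SgRNADesign], path) -> None:
    pd.DataFrame(
        {
            "gene": [d.gene for d in designs],
            "pam_site": [d.pam_site for d in designs],
            "n_mismatches": [d.n_mismatches for d in designs],
            "sequence": [d.targeting_seq for d in designs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_guide_table(path) -> list[SgRNADesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        SgRNADesign(r.gene, r.pam_site, r.sequence, int(r.n_mismatches))
        for r in df.itertuples()
    ]
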