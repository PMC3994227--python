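"""Multi-SNP genotype combination models, their fitness, and exhaustive search.

A *model* of order ``d`` is an ordered collection of ``d`` (SNP index,
genotype code) pairs.  An individual *matches* the model when it carries
every listed genotype.  A model's fitness is its carrier frequency among
cases minus its carrier frequency among controls — except that a model
naming the same SNP twice is assigned fitness 0 exactly.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .genotype_data import GenotypeDataset

__all__ = [
    "SNPModel",
    "FitnessValue",
    "is_valid_model",
    "sample_matches_model",
    "fitness",
    "enumerate_models",
    "model_count",
    "exhaustive_best",
]

_NOTATION_RE = re.compile(r"^SNP\((?P<snps>[\d,\s]+)\):(?P<codes>[\d-]+)$")


@dataclass(frozen=True)
class SNPModel:
    """An ordered set of (snp_index, genotype_code) pairs.

    SNP indices are 0-based internally; the text notation is 1-based,
    e.g. ``SNP(1,4):2-2`` for ``elements=((0, 2), (3, 2))``.
    """

    elements: tuple[tuple[int, int], ...]

    def __init__(self, elements) -> None:
        object.__setattr__(
            self, "elements", tuple((int(s), int(g)) for s, g in elements)
        )

    @property
    def order(self) -> int:
        return len(self.elements)

    @property
    def snp_indices(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.elements)

    @property
    def genotype_codes(self) -> tuple[int, ...]:
        return tuple(g for _, g in self.elements)

    def is_valid(self) -> bool:
        return is_valid_model(self)

    def canonical(self) -> "SNPModel":
        """Elements sorted by SNP index — identity for deduplication."""
        return SNPModel(sorted(self.elements))

    def notation(self) -> str:
        snps = ",".join(str(s + 1) for s in self.snp_indices)
        codes = "-".join(str(g) for g in self.genotype_codes)
        return f"SNP({snps}):{codes}"

    @classmethod
    def from_notation(cls, text: str) -> "SNPModel":
        m = _NOTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse model notation {text!r}")
        snps = [int(x) - 1 for x in m.group("snps").replace(" ", "").split(",")]
        codes = [int(x) for x in m.group("codes").split("-")]
        if len(snps) != len(codes):
            raise ValueError(f"{text!r}: SNP and genotype counts differ")
        return cls(zip(snps, codes))

    def __str__(self) -> str:
        return self.notation()


@dataclass(frozen=True)
class FitnessValue:
    """Signed case-minus-control carrier frequency difference."""

    value: float
    case_freq: float
    control_freq: float
    case_count: int
    control_count: int

    @property
    def percent(self) -> float:
        """Report-layer value: raw proportion difference x100, 2 decimals."""
        return round(100.0 * self.value, 2)


def is_valid_model(model: SNPModel) -> bool:
    """True iff no SNP index is repeated."""
    snps = model.snp_indices
    return len(set(snps)) == len(snps)


def sample_matches_model(model: SNPModel, sample_genotypes: Sequence[int]) -> int:
    """1 iff the sample carries every (SNP, genotype) in the model, else 0."""
    sample = np.asarray(sample_genotypes)
    return int(all(sample[s] == g for s, g in model.elements))


def _match_mask(model: SNPModel, genotypes: np.ndarray) -> np.ndarray:
    """Boolean match vector over the rows of a genotype matrix."""
    if not model.elements:
        return np.ones(genotypes.shape[0], dtype=bool)
    snps = list(model.snp_indices)
    codes = np.array(model.genotype_codes)
    return (genotypes[:, snps] == codes).all(axis=1)


def fitness(model: SNPModel, dataset: GenotypeDataset) -> FitnessValue:
    """Evaluate a model on a dataset.

    Returns case carrier frequency minus control carrier frequency, with the
    underlying counts; exactly 0.0 (and zero counts) for a model that
    repeats a SNP.
    """
    for s, _ in model.elements:
        if not 0 <= s < dataset.n_snps:
            raise IndexError(f"model references SNP index {s} outside dataset")
    if not is_valid_model(model):
        return FitnessValue(0.0, 0.0, 0.0, 0, 0)
    a = int(_match_mask(model, dataset.case_genotypes).sum())
    b = int(_match_mask(model, dataset.control_genotypes).sum())
    case_freq = a / dataset.n_case
    control_freq = b / dataset.n_control
    return FitnessValue(case_freq - control_freq, case_freq, control_freq, a, b)


def model_count(n_snps: int, n_genotypes: int, order: int) -> int:
    """Number of valid models: C(n_snps, order) * n_genotypes**order."""
    return math.comb(n_snps, order) * n_genotypes**order


def enumerate_models(
    n_snps: int, n_genotypes: int, order: int
) -> Iterator[SNPModel]:
    """Yield every valid model exactly once, in deterministic order.

    Lexicographic by the sorted SNP index tuple, then by genotype codes.
    """
    if not 1 <= order <= n_snps:
        raise ValueError(f"order {order} outside 1..{n_snps}")
    for snps in itertools.combinations(range(n_snps), order):
        for codes in itertools.product(range(1, n_genotypes + 1), repeat=order):
            yield SNPModel(zip(snps, codes))


def exhaustive_best(
    dataset: GenotypeDataset,
    order: int,
    k: int = 10,
    *,
    n_genotypes: int | None = None,
    ceiling: int = 10**7,
) -> list[tuple[SNPModel, FitnessValue]]:
    """Top-k valid models by signed fitness, via full enumeration.

    Ties are broken by enumeration order (stable sort).  Refuses to scan a
    space larger than ``ceiling`` models.
    """
    g = n_genotypes if n_genotypes is not None else dataset.n_genotypes
    total = model_count(dataset.n_snps, g, order)
    if total > ceiling:
        raise ValueError(
            f"model space of {total} exceeds enumeration ceiling {ceiling}"
        )
    scored = [
        (model, fitness(model, dataset))
        for model in enumerate_models(dataset.n_snps, g, order)
    ]
    scored.sort(key=lambda pair: -pair[1].value)
    return scored[: min(k, total)]
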