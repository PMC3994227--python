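import numpy as np
import pytest

from snpga import GenotypeDataset, SNPModel


def build_cohort_from_counts(
    model: SNPModel,
    case_positive: int,
    control_positive: int,
    n_case: int = 345,
    n_control: int = 290,
    n_snps: int = 5,
) -> GenotypeDataset:
    """Deterministic cohort in which exactly the given numbers of cases and
    controls match `model` and nobody else does.

    Matching rows carry the model's genotype codes at the model's SNPs;
    non-matching rows differ at the model's first SNP.  All remaining
    genotypes are code 1.
    """
    n = n_case + n_control
    genotypes = np.ones((n, n_snps), dtype=np.int64)
    labels = np.array(["case"] * n_case + ["control"] * n_control, dtype=object)
    first_snp, first_code = model.elements[0]
    off_code = first_code % 3 + 1  # any code != first_code
    for s, g in model.elements:
        genotypes[:, s] = g
    genotypes[case_positive:n_case, first_snp] = off_code
    genotypes[n_case + control_positive :, first_snp] = off_code
    return GenotypeDataset(genotypes=genotypes, labels=labels)


def build_single_snp_dataset(case_counts, control_counts) -> GenotypeDataset:
    """One-SNP cohort with the given per-genotype (code 1, 2, 3) counts."""
    codes = []
    labels = []
    for g, k in enumerate(case_counts, start=1):
        codes += [g] * k
        labels += ["case"] * k
    for g, k in enumerate(control_counts, start=1):
        codes += [g] * k
        labels += ["control"] * k
    return GenotypeDataset(
        genotypes=np.array(codes, dtype=np.int64)[:, None],
        labels=np.array(labels, dtype=object),
    )


@pytest.fixture
def best_2snp_model() -> SNPModel:
    return SNPModel.from_notation("SNP(1,4):2-2")


@pytest.fixture
def table3_2snp_cohort(best_2snp_model) -> GenotypeDataset:
    """Cohort realizing the printed best-2-SNP counts: 145/345 vs 101/290."""
    return build_cohort_from_counts(best_2snp_model, 145, 101)
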