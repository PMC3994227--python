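"""Case-control genotype datasets: loading, encoding, validation, synthesis.

Genotypes are coded as small integers per SNP: ``1`` = homozygous for the
major allele (the reference class), ``2`` = heterozygous, ``3`` = homozygous
for the minor allele.  A dataset is a dense ``N x S`` integer matrix plus a
per-individual case/control label; no missing values are permitted after
loading (rows containing any missing value are dropped and counted).
"""

from __future__ import annotations

import io
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .model_space import SNPModel

__all__ = [
    "GenotypeDataset",
    "SyntheticCohortSpec",
    "LoadReport",
    "encode_genotypes",
    "decode_genotype",
    "load_genotype_table",
    "generate_synthetic_cohort",
    "genotype_frequency_table",
]

CASE = "case"
CONTROL = "control"

#: Default number of genotype classes per biallelic SNP.
DEFAULT_N_GENOTYPES = 3


@dataclass
class LoadReport:
    """Row accounting for a table load."""

    rows_read: int = 0
    rows_dropped: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        kept = self.rows_read - self.rows_dropped
        return (
            f"read {self.rows_read} rows, dropped {self.rows_dropped} "
            f"with missing values, kept {kept}"
        )


@dataclass
class GenotypeDataset:
    """A coded genotype matrix with case/control labels.

    Parameters
    ----------
    genotypes
        Integer matrix of shape ``(n_individuals, n_snps)`` with values in
        ``1..n_genotypes``.
    labels
        Array of ``"case"`` / ``"control"`` strings, one per individual.
    snp_names
        Column identifiers, one per SNP.
    genotype_labels
        Optional per-SNP mapping ``code -> allele-pair string``
        (e.g. ``{1: "GG", 2: "GT", 3: "TT"}``), keyed by SNP name.
    n_genotypes
        Number of genotype classes (3 for biallelic SNPs).
    """

    genotypes: np.ndarray
    labels: np.ndarray
    snp_names: list[str] = field(default_factory=list)
    genotype_labels: dict[str, dict[int, str]] | None = None
    n_genotypes: int = DEFAULT_N_GENOTYPES
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if len(self.labels) != self.genotypes.shape[0]:
            raise ValueError("labels length does not match genotype rows")
        if not self.snp_names:
            self.snp_names = [f"SNP{j + 1}" for j in range(self.genotypes.shape[1])]
        if len(self.snp_names) != self.genotypes.shape[1]:
            raise ValueError("snp_names length does not match genotype columns")
        bad = set(self.labels) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown status value(s): {sorted(bad)}")
        if self.genotypes.size and (
            self.genotypes.min() < 1 or self.genotypes.max() > self.n_genotypes
        ):
            raise ValueError(
                f"genotype codes must lie in 1..{self.n_genotypes}; "
                f"found range [{self.genotypes.min()}, {self.genotypes.max()}]"
            )
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("dataset must contain at least one case and one control")

    # -- derived views -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return np.asarray(self.labels == CASE)

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_case).sum())

    @property
    def case_genotypes(self) -> np.ndarray:
        return self.genotypes[self.is_case]

    @property
    def control_genotypes(self) -> np.ndarray:
        return self.genotypes[~self.is_case]

    # -- I/O -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=self.snp_names)
        df.insert(0, "status", self.labels)
        return df

    def to_csv(self, path: str | os.PathLike | io.TextIOBase) -> None:
        """Canonical dump: integer codes, stable column order, no index."""
        self.to_frame().to_csv(path, index=False)


def encode_genotypes(
    allele_pairs,
    major_allele: str,
    minor_allele: str,
) -> np.ndarray:
    """Convert allele-pair strings to genotype codes 1/2/3.

    The pair is unordered (``"GT"`` and ``"TG"`` both code as 2).
    major/major -> 1, heterozygote -> 2, minor/minor -> 3.
    """
    if major_allele == minor_allele:
        raise ValueError("major and minor allele must differ")
    codes = np.empty(len(allele_pairs), dtype=np.int64)
    for i, pair in enumerate(allele_pairs):
        pair = str(pair).strip()
        if len(pair) != 2:
            raise ValueError(f"allele pair {pair!r} is not two characters")
        extra = set(pair) - {major_allele, minor_allele}
        if extra:
            raise ValueError(
                f"allele pair {pair!r} contains undeclared allele(s) {sorted(extra)}"
            )
        codes[i] = 1 + sum(ch == minor_allele for ch in pair)
    return codes


def decode_genotype(code: int, major_allele: str, minor_allele: str) -> str:
    """Inverse of :func:`encode_genotypes` for one code (canonical order)."""
    if code == 1:
        return major_allele + major_allele
    if code == 2:
        return major_allele + minor_allele
    if code == 3:
        return minor_allele + minor_allele
    raise ValueError(f"genotype code {code} outside 1..3")


def _infer_alleles(values: pd.Series, name: str) -> tuple[str, str]:
    """Infer (major, minor) from allele-pair strings by allele count."""
    counts: Counter[str] = Counter()
    for pair in values:
        counts.update(str(pair).strip())
    alleles = sorted(counts)
    if len(alleles) > 2:
        raise ValueError(f"SNP column {name!r} has >2 distinct alleles: {alleles}")
    if len(alleles) == 1:  # monomorphic column: minor allele unseen
        return alleles[0], "?"
    # major = most frequent; alphabetical tie-break for determinism
    (a, na), (b, nb) = counts.most_common(2)
    if na == nb:
        a, b = sorted((a, b))
    return a, b


def load_genotype_table(
    path,
    *,
    status_column: str = "status",
    alleles=None,
    sep: str | None = None,
    n_genotypes: int = DEFAULT_N_GENOTYPES,
) -> GenotypeDataset:
    """Load a CSV/TSV case-control genotype table.

    One row per individual; a status column with values ``case``/``control``;
    every other column is a SNP whose values are either integer codes
    ``1..n_genotypes`` or allele-pair strings (``"GT"``).  Rows containing
    missing values are dropped; the count is recorded on
    ``dataset.load_report``.

    Parameters
    ----------
    alleles
        Optional ``{snp_name: {"major": "G", "minor": "T"}}`` mapping, or a
        path to a YAML file with that layout.  Needed only to pin the
        major/minor assignment for allele-pair columns; when absent the
        major allele is inferred as the most frequent one.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read genotype table {path!r}: {exc}") from exc
    if status_column not in df.columns:
        raise ValueError(f"missing status column {status_column!r}")

    if isinstance(alleles, (str, os.PathLike)):
        with open(alleles) as fh:
            alleles = yaml.safe_load(fh)
    alleles = alleles or {}

    rows_read = len(df)
    df = df.dropna()
    if len(df):
        blank = (df.apply(lambda c: c.astype(str).str.strip()) == "").any(axis=1)
        df = df[~blank]
    report = LoadReport(rows_read=rows_read, rows_dropped=rows_read - len(df))

    labels = df[status_column].str.strip().str.lower().to_numpy()
    snp_names = [c for c in df.columns if c != status_column]
    genotype_labels: dict[str, dict[int, str]] = {}
    columns = []
    for name in snp_names:
        col = df[name].astype(str).str.strip()
        if col.str.fullmatch(r"\d+").all():
            codes = col.astype(int).to_numpy()
            if codes.size and (codes.min() < 1 or codes.max() > n_genotypes):
                raise ValueError(
                    f"SNP column {name!r}: genotype code outside 1..{n_genotypes}"
                )
        else:
            if name in alleles:
                major, minor = alleles[name]["major"], alleles[name]["minor"]
            else:
                major, minor = _infer_alleles(col, name)
            codes = encode_genotypes(col.to_numpy(), major, minor)
            genotype_labels[name] = {
                g: decode_genotype(g, major, minor) for g in (1, 2, 3)
            }
        columns.append(codes)
    genotypes = (
        np.column_stack(columns) if columns else np.empty((len(df), 0), dtype=np.int64)
    )
    return GenotypeDataset(
        genotypes=genotypes,
        labels=labels,
        snp_names=snp_names,
        genotype_labels=genotype_labels or None,
        n_genotypes=n_genotypes,
        load_report=report,
    )


@dataclass
class SyntheticCohortSpec:
    """Recipe for a synthetic case-control cohort.

    Background genotypes follow per-SNP Hardy-Weinberg proportions given the
    control minor-allele frequencies.  If ``embedded_model`` is set, each
    individual's genotypes at the model's SNPs are overwritten with the
    model's codes with probability ``target_freq_case`` (cases) or
    ``target_freq_control`` (controls); background individuals may still
    match the model by chance.
    """

    n_case: int
    n_control: int
    snp_mafs: tuple[float, ...]
    embedded_model: "SNPModel | None" = None
    target_freq_case: float = 0.0
    target_freq_control: float = 0.0
    seed: int = 0
    snp_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")
        self.snp_mafs = tuple(float(m) for m in self.snp_mafs)
        if not self.snp_mafs:
            raise ValueError("need at least one SNP")
        for m in self.snp_mafs:
            if not 0.0 < m < 0.5:
                raise ValueError(f"MAF {m} outside (0, 0.5)")
        if self.embedded_model is not None:
            if not 0.0 <= self.target_freq_control <= self.target_freq_case <= 1.0:
                raise ValueError(
                    "need 0 <= target_freq_control <= target_freq_case <= 1"
                )
            for snp, _ in self.embedded_model.elements:
                if not 0 <= snp < len(self.snp_mafs):
                    raise ValueError(f"embedded model SNP {snp} out of range")


def generate_synthetic_cohort(spec: SyntheticCohortSpec) -> GenotypeDataset:
    """Draw a cohort per ``spec``; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    s = len(spec.snp_mafs)
    genotypes = np.empty((n, s), dtype=np.int64)
    for j, maf in enumerate(spec.snp_mafs):
        # HWE class probabilities for codes (1, 2, 3)
        p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        genotypes[:, j] = rng.choice([1, 2, 3], size=n, p=p)
    labels = np.array([CASE] * spec.n_case + [CONTROL] * spec.n_control, dtype=object)
    if spec.embedded_model is not None:
        carrier = np.empty(n, dtype=bool)
        carrier[: spec.n_case] = rng.random(spec.n_case) < spec.target_freq_case
        carrier[spec.n_case :] = rng.random(spec.n_control) < spec.target_freq_control
        for snp, code in spec.embedded_model.elements:
            genotypes[carrier, snp] = code
    return GenotypeDataset(
        genotypes=genotypes,
        labels=labels,
        snp_names=spec.snp_names or [f"SNP{j + 1}" for j in range(s)],
    )


def genotype_frequency_table(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP, per-genotype case/control counts and group percentages.

    Counts for each SNP sum to the case and control group sizes; percentages
    are of the group totals, rounded to 2 decimals at this report layer.
    """
    rows = []
    case = dataset.case_genotypes
    ctrl = dataset.control_genotypes
    for j, name in enumerate(dataset.snp_names):
        labels = (dataset.genotype_labels or {}).get(name, {})
        for g in range(1, dataset.n_genotypes + 1):
            a = int((case[:, j] == g).sum())
            b = int((ctrl[:, j] == g).sum())
            rows.append(
                {
                    "snp": name,
                    "genotype_code": g,
                    "genotype": labels.get(g, str(g)),
                    "case_n": a,
                    "case_pct": round(100.0 * a / dataset.n_case, 2),
                    "control_n": b,
                    "control_pct": round(100.0 * b / dataset.n_control, 2),
                }
            )
    return pd.DataFrame(rows)
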