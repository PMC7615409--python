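"""Reading, validation, harmonization and covariance-scale transforms.

GWAS summary files carry per-allele marginal betas; the estimators in
this package consume variant-trait *covariances* delta_j = beta_j *
var(Z_j).  This module harmonizes exposure/outcome/LD inputs into a
:class:`SummaryDataset` on that scale, together with the variant
covariance matrix derived from an LD correlation matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SummaryDataError(ValueError):
    """Malformed or inconsistent summary-data input."""


@dataclass(frozen=True)
class VariantRecord:
    """One row of a GWAS summary-association table."""

    variant_id: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise SummaryDataError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in _VALID_ALLELES:
            raise SummaryDataError(
                f"{self.variant_id}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.variant_id}: effect and other allele are identical")
        if self.se < 0:
            raise SummaryDataError(f"{self.variant_id}: negative standard error")
        if self.n < 2:
            raise SummaryDataError(f"{self.variant_id}: sample size must be >= 2")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC


@dataclass
class LDMatrix:
    """Variant correlation matrix with matching variant order."""

    variant_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        p = len(self.variant_ids)
        if self.rho.shape != (p, p):
            raise SummaryDataError(
                f"LD matrix shape {self.rho.shape} does not match {p} variant ids"
            )
        if not np.allclose(self.rho, self.rho.T, atol=1e-8):
            raise SummaryDataError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-6):
            raise SummaryDataError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.rho) > 1 + 1e-8):
            raise SummaryDataError("LD matrix entries must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.variant_ids)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        idx = np.array([index[v] for v in ids], dtype=int)
        return LDMatrix(list(ids), self.rho[np.ix_(idx, idx)])


@dataclass
class VariantCovariance:
    """Positive-semidefinite estimate of var(Z)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise SummaryDataError("variant covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise SummaryDataError("variant covariance must be symmetric")

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SummaryDataset:
    """Harmonized two-sample summary data on the covariance scale."""

    variant_ids: list[str]
    delta_x: np.ndarray
    delta_y: np.ndarray
    n_x: int
    n_y: int
    var_x: float
    var_y: float
    variant_variances: np.ndarray

    def __post_init__(self) -> None:
        self.delta_x = np.asarray(self.delta_x, dtype=float)
        self.delta_y = np.asarray(self.delta_y, dtype=float)
        self.variant_variances = np.asarray(self.variant_variances, dtype=float)
        p = len(self.variant_ids)
        for name in ("delta_x", "delta_y", "variant_variances"):
            vec = getattr(self, name)
            if vec.shape != (p,):
                raise SummaryDataError(f"{name} has shape {vec.shape}, expected ({p},)")
        if self.var_x <= 0 or self.var_y <= 0:
            raise SummaryDataError("trait variances must be positive")
        if np.any(self.variant_variances <= 0):
            raise SummaryDataError("variant variances must be positive")

    @property
    def p(self) -> int:
        return len(self.variant_ids)

    def to_files(self, tsv_path: str | Path, json_path: str | Path) -> None:
        """Write the vector data as TSV and the scalars as a JSON sidecar."""
        frame = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "delta_x": self.delta_x,
                "delta_y": self.delta_y,
                "variant_variance": self.variant_variances,
            }
        )
        frame.to_csv(tsv_path, sep="\t", index=False)
        scalars = {
            "n_x": self.n_x, "n_y": self.n_y,
            "var_x": self.var_x, "var_y": self.var_y,
        }
        Path(json_path).write_text(json.dumps(scalars, indent=2))

    @classmethod
    def from_files(cls, tsv_path: str | Path, json_path: str | Path) -> "SummaryDataset":
        frame = pd.read_csv(tsv_path, sep="\t")
        scalars = json.loads(Path(json_path).read_text())
        return cls(
            variant_ids=list(frame["variant_id"].astype(str)),
            delta_x=frame["delta_x"].to_numpy(),
            delta_y=frame["delta_y"].to_numpy(),
            n_x=int(scalars["n_x"]),
            n_y=int(scalars["n_y"]),
            var_x=float(scalars["var_x"]),
            var_y=float(scalars["var_y"]),
            variant_variances=frame["variant_variance"].to_numpy(),
        )


_CANONICAL_COLUMNS = ("variant_id", "position", "effect_allele", "other_allele", "beta", "se", "n")


def read_summary_associations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a TSV of per-variant associations into :class:`VariantRecord` rows.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from canonical names (``variant_id``, ``position``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``n``) to the
        column names actually present in the file.

    Rows with missing ``beta`` or ``se`` are dropped; the count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    column_map = dict(column_map or {})
    rename = {}
    for canonical in _CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in frame.columns:
            raise SummaryDataError(f"{path}: required column {source!r} not found")
        rename[source] = canonical
    frame = frame.rename(columns=rename)[list(_CANONICAL_COLUMNS)]
    n_before = len(frame)
    frame = frame.dropna(subset=["beta", "se"])
    n_dropped = n_before - len(frame)
    if n_dropped:
        logger.info("%s: dropped %d rows with missing beta/se", path, n_dropped)
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            VariantRecord(
                variant_id=str(row.variant_id),
                position=int(row.position),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                beta=float(row.beta),
                se=float(row.se),
                n=int(row.n),
            )
        )
    return records


@dataclass
class HarmonizedData:
    """Aligned exposure/outcome records in LD-matrix order."""

    exposure: list[VariantRecord]
    outcome: list[VariantRecord]
    ld: LDMatrix
    n_palindromic_dropped: int = 0
    n_irreconcilable_dropped: int = 0

    @property
    def variant_ids(self) -> list[str]:
        return [rec.variant_id for rec in self.exposure]


def _alleles_match(a: VariantRecord, b: VariantRecord) -> str:
    """Return 'same', 'swap' or 'none' for the allele orientation of b vs a."""
    if (a.effect_allele, a.other_allele) == (b.effect_allele, b.other_allele):
        return "same"
    if (a.effect_allele, a.other_allele) == (b.other_allele, b.effect_allele):
        return "swap"
    return "none"


def harmonize(
    exposure: Sequence[VariantRecord],
    outcome: Sequence[VariantRecord],
    ld: LDMatrix,
) -> HarmonizedData:
    """Align exposure and outcome records to a common variant set and order.

    The output is restricted to the intersection of the three sources, in
    LD-matrix order.  Outcome records whose alleles are swapped relative to
    the exposure have their beta sign flipped.  Strand-ambiguous palindromic
    variants (A/T, C/G) are dropped unconditionally, as are variants whose
    allele pairs cannot be reconciled.
    """
    exp_by_id = {rec.variant_id: rec for rec in exposure}
    out_by_id = {rec.variant_id: rec for rec in outcome}
    common = [v for v in ld.variant_ids if v in exp_by_id and v in out_by_id]
    if not common:
        raise SummaryDataError("no variants shared across exposure, outcome and LD matrix")

    kept_exp: list[VariantRecord] = []
    kept_out: list[VariantRecord] = []
    n_palindromic = 0
    n_irreconcilable = 0
    for vid in common:
        e = exp_by_id[vid]
        o = out_by_id[vid]
        if e.is_palindromic or o.is_palindromic:
            n_palindromic += 1
            continue
        orientation = _alleles_match(e, o)
        if orientation == "none":
            logger.warning("%s: allele pair irreconcilable, variant dropped", vid)
            n_irreconcilable += 1
            continue
        if orientation == "swap":
            o = VariantRecord(
                variant_id=o.variant_id,
                position=o.position,
                effect_allele=o.other_allele,
                other_allele=o.effect_allele,
                beta=-o.beta,
                se=o.se,
                n=o.n,
            )
        kept_exp.append(e)
        kept_out.append(o)
    if not kept_exp:
        raise SummaryDataError("harmonization dropped every shared variant")
    ids = [rec.variant_id for rec in kept_exp]
    return HarmonizedData(
        exposure=kept_exp,
        outcome=kept_out,
        ld=ld.subset(ids),
        n_palindromic_dropped=n_palindromic,
        n_irreconcilable_dropped=n_irreconcilable,
    )


def beta_to_covariance(beta: np.ndarray, variant_variances: np.ndarray) -> np.ndarray:
    """Convert per-allele marginal betas to variant-trait covariances.

    For a univariable regression of a trait on allele count Z_j, the
    coefficient is cov(Z_j, trait)/var(Z_j), so delta_j = beta_j * var(Z_j).
    """
    beta = np.asarray(beta, dtype=float)
    variances = np.asarray(variant_variances, dtype=float)
    if np.any(variances <= 0):
        raise SummaryDataError("variant variances must be positive")
    return beta * variances


def variance_from_frequency(freq: np.ndarray) -> np.ndarray:
    """Allele-dosage variance 2 f (1 - f) under Hardy-Weinberg equilibrium."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq <= 0) or np.any(freq >= 1):
        raise SummaryDataError("allele frequencies must lie strictly in (0, 1)")
    return 2.0 * freq * (1.0 - freq)


def logit_to_linear(beta_logit: np.ndarray, case_fraction: float) -> np.ndarray:
    """First-order conversion of logit coefficients to linear-model scale.

    For a binary outcome with prevalence mu and small per-variant effects,
    the linear-regression coefficient is approximately beta_logit * mu * (1 - mu).
    """
    if not 0 < case_fraction < 1:
        raise SummaryDataError("case fraction must lie strictly in (0, 1)")
    return np.asarray(beta_logit, dtype=float) * case_fraction * (1.0 - case_fraction)


def nearest_psd(matrix: np.ndarray, floor_scale: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to PSD by clipping eigenvalues.

    Eigenvalues are clipped at ``floor_scale`` times the largest eigenvalue.
    An already-PSD input is returned unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise SummaryDataError("nearest_psd requires a symmetric matrix")
    matrix = 0.5 * (matrix + matrix.T)
    eigvals, eigvecs = np.linalg.eigh(matrix)
    lo = floor_scale * max(eigvals[-1], 0.0)
    if eigvals[0] >= lo:
        return matrix
    clipped = np.clip(eigvals, lo, None)
    repaired = (eigvecs * clipped) @ eigvecs.T
    return 0.5 * (repaired + repaired.T)


def build_variant_covariance(
    ld: LDMatrix, variant_variances: np.ndarray
) -> VariantCovariance:
    """Scale an LD correlation matrix by variant variances, then PSD-repair."""
    variances = np.asarray(variant_variances, dtype=float)
    if variances.shape != (ld.p,):
        raise SummaryDataError(
            f"variant variances shape {variances.shape} does not match p = {ld.p}"
        )
    if np.any(variances <= 0):
        raise SummaryDataError("variant variances must be positive")
    sd = np.sqrt(variances)
    cov = ld.rho * np.outer(sd, sd)
    return VariantCovariance(nearest_psd(cov))


def build_summary_dataset(
    harmonized: HarmonizedData,
    variant_variances: np.ndarray | None,
    var_x: float,
    var_y: float,
    *,
    allele_frequencies: np.ndarray | None = None,
    case_fraction: float | None = None,
) -> tuple[SummaryDataset, VariantCovariance]:
    """Assemble covariance-scale summary data and the variant covariance.

    Variant variances may be supplied directly or derived from allele
    frequencies under Hardy-Weinberg.  When ``case_fraction`` is given the
    outcome betas are treated as logit coefficients and converted to the
    linear scale first.
    """
    if variant_variances is None:
        if allele_frequencies is None:
            raise SummaryDataError(
                "either variant_variances or allele_frequencies must be supplied"
            )
        variant_variances = variance_from_frequency(allele_frequencies)
    variant_variances = np.asarray(variant_variances, dtype=float)

    beta_x = np.array([rec.beta for rec in harmonized.exposure])
    beta_y = np.array([rec.beta for rec in harmonized.outcome])
    if case_fraction is not None:
        beta_y = logit_to_linear(beta_y, case_fraction)

    n_x = int(np.median([rec.n for rec in harmonized.exposure]))
    n_y = int(np.median([rec.n for rec in harmonized.outcome]))

    dataset = SummaryDataset(
        variant_ids=harmonized.variant_ids,
        delta_x=beta_to_covariance(beta_x, variant_variances),
        delta_y=beta_to_covariance(beta_y, variant_variances),
        n_x=n_x,
        n_y=n_y,
        var_x=var_x,
        var_y=var_y,
        variant_variances=variant_variances,
    )
    varz = build_variant_covariance(harmonized.ld, variant_variances)
    return dataset, varz


def read_ld_matrix(path: str | Path, fmt: str = "auto") -> LDMatrix:
    """Read an LD matrix from a square-matrix TSV or a long-format TSV.

    Square format: header row of variant IDs, one data row per variant
    (whitespace or comma delimited).  Long format: three columns
    ``id1``, ``id2``, ``r``; missing pairs default to 0, the diagonal to 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        with open(path) as fh:
            header = fh.readline()
        cols = header.replace(",", "\t").split()
        fmt = "long" if [c.lower() for c in cols[:3]] == ["id1", "id2", "r"] else "square"
    if fmt == "square":
        frame = pd.read_csv(path, sep=None, engine="python")
        ids = [str(c) for c in frame.columns]
        return LDMatrix(ids, frame.to_numpy(dtype=float))
    if fmt == "long":
        frame = pd.read_csv(path, sep=None, engine="python")
        frame.columns = [c.lower() for c in frame.columns]
        ids = sorted(set(frame["id1"].astype(str)) | set(frame["id2"].astype(str)))
        index = {v: i for i, v in enumerate(ids)}
        rho = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(rho, 1.0)
        for row in frame.itertuples(index=False):
            i, j = index[str(row.id1)], index[str(row.id2)]
            rho[i, j] = rho[j, i] = float(row.r)
        return LDMatrix(ids, rho)
    raise SummaryDataError(f"unknown LD matrix format {fmt!r}")


def cis_window(
    records: Sequence[VariantRecord],
    gene_start: int,
    gene_end: int,
    window_kb: float = 100.0,
) -> list[VariantRecord]:
    """Restrict records to the closed window [gene_start - W, gene_end + W]."""
    w = int(round(window_kb * 1000))
    lo, hi = gene_start - w, gene_end + w
    return [rec for rec in records if lo <= rec.position <= hi]
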