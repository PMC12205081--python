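"""Label-free enrichment statistics for proximity-labeling and IP-MS arms.

Quantification follows the top-3 rule: a protein's area in a replicate is
the mean of its three most intense peptides in that replicate.  Missing
protein-level values are replaced by one global constant, the average of the
per-replicate-column minima.  Two enrichment arms share the quantification:

* ``turboid`` (proximity labeling): fold change of mean bait over mean
  control area; enriched iff log2 fold change >= 1;
* ``ipms`` (immunoprecipitation): the same fold-change rule combined with an
  empirical-Bayes moderated t-test on log2 areas (variance shrinkage toward
  a pooled prior fitted by method of moments on the log sample variances)
  and Benjamini–Hochberg adjustment; enriched iff adjusted p < 0.05 and
  log2 fold change >= 1.

A planted-truth synthetic generator emulates protein x replicate tables
with log-normal areas, a known enriched subset, and configurable
missingness (censoring of low-abundance cells or completely at random).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

BAIT, CONTROL = "bait", "control"


# --------------------------------------------------------------------------
# Tables


def _check_peptide_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"protein", "peptide", "replicate", "condition", "area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peptide table lacks columns {sorted(missing)}")
    bad = set(table["condition"].unique()) - {BAIT, CONTROL}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    if (table["area"].dropna() <= 0).any():
        raise ValueError("peptide areas must be positive where present")
    return table


@dataclass
class ProteinQuant:
    """Protein × (condition, replicate) area matrix.

    ``areas`` has a protein index and a two-level column index
    ``(condition, replicate)``; NaN marks missing cells until imputation.
    """

    areas: pd.DataFrame
    provenance: str = "direct"  # direct | from_peptides
    imputed_value: Optional[float] = None
    n_imputed: int = 0

    def __post_init__(self):
        if self.areas.columns.nlevels != 2:
            raise ValueError("areas needs (condition, replicate) columns")
        conds = set(self.areas.columns.get_level_values(0))
        if not conds <= {BAIT, CONTROL}:
            raise ValueError(f"unknown conditions {sorted(conds - {BAIT, CONTROL})}")
        vals = self.areas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise ValueError("areas must be positive where present")

    def condition(self, cond: str) -> pd.DataFrame:
        return self.areas[cond]

    @property
    def has_missing(self) -> bool:
        return bool(self.areas.isna().any().any())


@dataclass
class ImputationSummary:
    value: float
    n_imputed: int
    column_minima: dict


# --------------------------------------------------------------------------
# Quantification


def top3_protein_area(table: pd.DataFrame,
                      per_replicate: bool = True) -> ProteinQuant:
    """Top-3 label-free quantification of a peptide-level area table.

    For every protein and replicate, the protein area is the mean of the
    three largest peptide areas observed in that replicate (all of them if
    fewer than three); cells with no observed peptides stay missing.  With
    ``per_replicate=False`` the top three peptides are instead chosen once
    per protein/condition by their replicate-averaged area.
    """
    table = _check_peptide_table(table)
    obs = table.dropna(subset=["area"])

    if per_replicate:
        def top3(series: pd.Series) -> float:
            return float(series.nlargest(3).mean())
        grouped = obs.groupby(["protein", "condition", "replicate"])["area"] \
            .apply(top3)
    else:
        mean_pep = obs.groupby(["protein", "condition", "peptide"])["area"] \
            .mean().rename("pepmean").reset_index()
        keep = mean_pep.groupby(["protein", "condition"])["pepmean"] \
            .nlargest(3).reset_index()[["protein", "condition", "pepmean"]]
        sel = mean_pep.merge(keep, on=["protein", "condition", "pepmean"])
        chosen = sel[["protein", "condition", "peptide"]]
        grouped = obs.merge(chosen, on=["protein", "condition", "peptide"]) \
            .groupby(["protein", "condition", "replicate"])["area"].mean()

    wide = grouped.unstack(["condition", "replicate"])
    wide = wide.sort_index(axis=1)
    return ProteinQuant(areas=wide, provenance="from_peptides")


def impute_missing(quant: ProteinQuant) -> tuple[ProteinQuant, ImputationSummary]:
    """Replace every missing cell by the average of per-column minima.

    The impute constant is the mean over replicate columns of the smallest
    observed area in that column; each replicate column must contain at
    least one observation.
    """
    areas = quant.areas.copy()
    minima = areas.min(axis=0, skipna=True)
    if minima.isna().any():
        empty = [c for c in areas.columns[minima.isna()]]
        raise ValueError(f"replicate columns with no observed values: {empty}")
    value = float(minima.mean())
    n_missing = int(areas.isna().sum().sum())
    filled = areas.fillna(value)
    summary = ImputationSummary(value=value, n_imputed=n_missing,
                                column_minima={f"{c}_{r}": float(v)
                                               for (c, r), v in minima.items()})
    return ProteinQuant(areas=filled, provenance=quant.provenance,
                        imputed_value=value, n_imputed=n_missing), summary


# --------------------------------------------------------------------------
# Enrichment calls


def _fold_change_frame(quant: ProteinQuant) -> pd.DataFrame:
    if quant.has_missing:
        raise ValueError("impute missing values before enrichment calls")
    for cond in (BAIT, CONTROL):
        if cond not in quant.areas.columns.get_level_values(0):
            raise ValueError(f"condition {cond!r} absent from table")
    mean_bait = quant.condition(BAIT).mean(axis=1)
    mean_control = quant.condition(CONTROL).mean(axis=1)
    log2fc = np.log2(mean_bait / mean_control)
    return pd.DataFrame({
        "mean_bait": mean_bait,
        "mean_control": mean_control,
        "log2_fold_change": log2fc,
    })


def fold_change_call(quant: ProteinQuant) -> pd.DataFrame:
    """TurboID-arm enrichment: enriched iff log2 fold change >= 1."""
    out = _fold_change_frame(quant)
    out["moderated_t"] = np.nan
    out["p_value"] = np.nan
    out["adjusted_p"] = np.nan
    out["enriched"] = out["log2_fold_change"] >= 1.0
    out["arm"] = "turboid"
    return out


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class ModeratedFit:
    """Empirical-Bayes variance shrinkage summary."""

    d0: float         # prior degrees of freedom (may be inf)
    s0_sq: float      # prior variance
    df_residual: float
    df_total: float


def fit_variance_prior(variances: np.ndarray, df: float) -> ModeratedFit:
    """Method-of-moments fit of (d0, s0²) on log sample variances.

    ``e = log(s²) - digamma(df/2) + log(df/2)`` has mean ``log(s0²) +
    digamma(d0/2) - log(d0/2)`` and variance ``trigamma(df/2) +
    trigamma(d0/2)`` under the hierarchical model; matching both moments
    yields the prior.  Zero variances are excluded from the fit.
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < 2:
        return ModeratedFit(d0=np.inf, s0_sq=float(np.mean(v)) if len(v) else 0.0,
                            df_residual=df, df_total=np.inf)
    e = np.log(v) - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    evar = float(e.var(ddof=1)) * (len(e) - 1) / len(e)  # population variance
    target = evar - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        d0 = np.inf
        s0 = float(np.exp(ebar))
    else:
        half_d0 = _trigamma_inverse(target)
        d0 = 2.0 * half_d0
        s0 = float(np.exp(ebar + special.digamma(half_d0) - np.log(half_d0)))
    return ModeratedFit(d0=d0, s0_sq=s0, df_residual=df,
                        df_total=df + d0 if np.isfinite(d0) else np.inf)


def moderated_test(quant: ProteinQuant, alpha: float = 0.05) -> pd.DataFrame:
    """IP-MS-arm enrichment: moderated t on log2 areas + BH adjustment.

    Per protein, a two-sample comparison of log2 bait vs control areas with
    the pooled within-group variance shrunk toward the empirical-Bayes
    prior: ``s̃² = (d0 s0² + d s²) / (d0 + d)``, ``t = Δmean / (s̃ sqrt(1/n1
    + 1/n2))`` on ``d + d0`` degrees of freedom.  Enriched iff adjusted
    p < ``alpha`` and log2 fold change >= 1 (fold change from raw means, as
    in the turboid arm).
    """
    out = _fold_change_frame(quant)
    b = np.log2(quant.condition(BAIT).to_numpy(dtype=float))
    c = np.log2(quant.condition(CONTROL).to_numpy(dtype=float))
    n1, n2 = b.shape[1], c.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated test needs >= 2 replicates per condition")
    df = float(n1 + n2 - 2)
    diff = b.mean(axis=1) - c.mean(axis=1)
    ss = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((c - c.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df

    prior = fit_variance_prior(s2, df)
    if np.isfinite(prior.d0):
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    else:
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    adj = multipletests(p, method="fdr_bh")[1]

    out["moderated_t"] = t
    out["p_value"] = p
    out["adjusted_p"] = adj
    out["enriched"] = (out["adjusted_p"] < alpha) & (out["log2_fold_change"] >= 1.0)
    out["arm"] = "ipms"
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s0_sq"] = prior.s0_sq
    return out


# --------------------------------------------------------------------------
# Synthetic generator


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Planted-truth protein × replicate abundance table.

    Log2 areas are Gaussian around a protein-specific baseline; the first
    ``n_enriched`` proteins carry a true bait-over-control log2 effect.
    Missingness is either censoring of the lowest cells (``MNAR-low``) or
    completely at random (``MCAR``).
    """

    n_proteins: int = 1000
    n_enriched: int = 100
    log2_effect: float = 2.0
    n_replicates: int = 4
    sigma: float = 0.5            # log2-scale replicate noise
    missing_rate: float = 0.05
    missing_mechanism: str = "MNAR-low"
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_enriched > self.n_proteins:
            raise ValueError("n_enriched must not exceed n_proteins")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.missing_mechanism not in ("MNAR-low", "MCAR"):
            raise ValueError("missing_mechanism must be MNAR-low or MCAR")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def simulate_protein_table(spec: SyntheticProteomeSpec) -> tuple[ProteinQuant, np.ndarray]:
    """Generate a protein-level quant table plus the planted-truth mask."""
    rng = np.random.default_rng(spec.seed)
    n, r = spec.n_proteins, spec.n_replicates
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=n)
    truth = np.zeros(n, dtype=bool)
    truth[:spec.n_enriched] = True
    effect = np.where(truth, spec.log2_effect, 0.0)

    log2_bait = base[:, None] + effect[:, None] + rng.normal(0, spec.sigma, (n, r))
    log2_ctrl = base[:, None] + rng.normal(0, spec.sigma, (n, r))
    log2_all = np.concatenate([log2_bait, log2_ctrl], axis=1)

    flat = log2_all.ravel()
    n_missing = int(round(spec.missing_rate * flat.size))
    miss = np.zeros(flat.size, dtype=bool)
    if n_missing:
        if spec.missing_mechanism == "MNAR-low":
            miss[np.argsort(flat)[:n_missing]] = True
        else:
            miss[rng.choice(flat.size, n_missing, replace=False)] = True
    areas = np.power(2.0, log2_all)
    areas[miss.reshape(log2_all.shape)] = np.nan

    proteins = [f"P{i:05d}" for i in range(n)]
    cols = pd.MultiIndex.from_tuples(
        [(BAIT, k + 1) for k in range(r)] + [(CONTROL, k + 1) for k in range(r)],
        names=["condition", "replicate"])
    df = pd.DataFrame(areas, index=pd.Index(proteins, name="protein"),
                      columns=cols)
    return ProteinQuant(areas=df, provenance="direct"), truth


def simulate_peptide_table(spec: SyntheticProteomeSpec,
                           mean_peptides: float = 6.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a peptide-level area table for the same planted truth.

    Each protein gets a Poisson number of peptides (at least one) with
    fixed per-peptide ionization factors; replicate areas multiply the
    protein abundance, the peptide factor, and log-normal noise.
    """
    quant, truth = simulate_protein_table(
        SyntheticProteomeSpec(**{**spec.__dict__, "missing_rate": 0.0}))
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for prot, row in quant.areas.iterrows():
        n_pep = max(1, int(rng.poisson(mean_peptides)))
        factors = np.power(2.0, rng.normal(0.0, 1.0, n_pep))
        for p in range(n_pep):
            for (cond, rep), area in row.items():
                noisy = area * factors[p] * np.power(2.0, rng.normal(0, 0.3))
                rows.append((prot, f"{prot}_pep{p}", rep, cond, noisy))
    df = pd.DataFrame(rows, columns=["protein", "peptide", "replicate",
                                     "condition", "area"])
    if spec.missing_rate > 0:
        flat = np.log2(df["area"].to_numpy())
        n_missing = int(round(spec.missing_rate * len(df)))
        miss = np.zeros(len(df), dtype=bool)
        if spec.missing_mechanism == "MNAR-low":
            miss[np.argsort(flat)[:n_missing]] = True
        else:
            miss[rng.choice(len(df), n_missing, replace=False)] = True
        df.loc[miss, "area"] = np.nan
    return df, truth


def enrichment_pipeline(quant: ProteinQuant, arm: str) -> pd.DataFrame:
    """Impute then call enrichment for the requested arm."""
    imputed, _ = impute_missing(quant)
    if arm == "turboid":
        return fold_change_call(imputed)
    if arm == "ipms":
        return moderated_test(imputed)
    raise ValueError("arm must be 'turboid' or 'ipms'")
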