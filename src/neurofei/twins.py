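"""ACE variance decomposition for twin phenotypes.

The classical twin design compares monozygotic (MZ) and dizygotic (DZ)
twin-pair covariance to split phenotypic variance into additive genetic
(A), common environmental (C), and unique environmental (E) components.
Latent factor A correlates 1 between MZ twins and 0.5 between DZ twins;
C correlates 1 in both; E is uncorrelated.  With path loadings a, c, e the
within-pair covariance matrix is::

    [[a2 + c2 + e2,  rA*a2 + c2 ],
     [rA*a2 + c2,   a2 + c2 + e2]]      rA = 1 (MZ) or 0.5 (DZ)

Heritability is a2 / (a2 + c2 + e2) (simplified to a2 / (a2 + e2) when C is
non-significant).  Parameters are obtained by maximum likelihood over
bivariate-normal pair likelihoods with age and sex as mean covariates, and
component significance by likelihood-ratio tests against the chi-square(1)
reference (a conservative 50:50 chi2(0)/chi2(1) boundary mixture is
available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, pearsonr

__all__ = [
    "TwinSample",
    "ACEModel",
    "ACEResults",
    "simulate_twins",
    "falconer_h2",
]


@dataclass(frozen=True)
class TwinSample:
    """Complete twin pairs with zygosity labels and per-twin covariates.

    Arrays are aligned per pair: ``y1``/``y2`` are the phenotype values of
    twin 1 and twin 2, ``mz`` flags monozygotic pairs, and ``age1``/
    ``age2``/``sex1``/``sex2`` carry the mean-model covariates (sex coded
    0/1).  Pairs with a missing phenotype in either twin are dropped at
    construction (pairwise deletion per phenotype); the effective counts
    are exposed as ``n_mz``/``n_dz``.
    """

    y1: np.ndarray
    y2: np.ndarray
    mz: np.ndarray
    age1: np.ndarray | None = None
    age2: np.ndarray | None = None
    sex1: np.ndarray | None = None
    sex2: np.ndarray | None = None

    def __post_init__(self) -> None:
        y1 = np.asarray(self.y1, dtype=np.float64)
        y2 = np.asarray(self.y2, dtype=np.float64)
        mz = np.asarray(self.mz, dtype=bool)
        if not (y1.size == y2.size == mz.size):
            raise ValueError("y1, y2 and mz must have equal length")
        covs = {}
        for name in ("age1", "age2", "sex1", "sex2"):
            v = getattr(self, name)
            covs[name] = None if v is None else np.asarray(v, dtype=np.float64)
            if covs[name] is not None and covs[name].size != y1.size:
                raise ValueError(f"{name} length does not match phenotypes")
        keep = np.isfinite(y1) & np.isfinite(y2)
        object.__setattr__(self, "y1", y1[keep])
        object.__setattr__(self, "y2", y2[keep])
        object.__setattr__(self, "mz", mz[keep])
        for name, v in covs.items():
            object.__setattr__(self, name, None if v is None else v[keep])

    @property
    def n_pairs(self) -> int:
        return int(self.y1.size)

    @property
    def n_mz(self) -> int:
        return int(self.mz.sum())

    @property
    def n_dz(self) -> int:
        return int((~self.mz).sum())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        phenotype: str = "phenotype",
        pair_id: str = "pair_id",
        zygosity: str = "zygosity",
        twin: str = "twin",
        age: str = "age",
        sex: str = "sex",
    ) -> "TwinSample":
        """Build a sample from a tidy long table (one row per individual).

        ``zygosity`` holds ``"MZ"``/``"DZ"`` labels and ``twin`` the 1/2
        index within the pair; incomplete pairs are dropped.
        """
        has_cov = age in df.columns and sex in df.columns
        wide = df.pivot_table(
            index=pair_id, columns=twin,
            values=[phenotype] + ([age, sex] if has_cov else []),
            aggfunc="first",
        )
        zyg = df.groupby(pair_id)[zygosity].first().reindex(wide.index)
        bad = ~zyg.isin(["MZ", "DZ"])
        if bad.any():
            raise ValueError(
                f"unknown zygosity labels: {sorted(zyg[bad].unique())}"
            )
        complete = wide[phenotype].notna().all(axis=1)
        wide, zyg = wide[complete], zyg[complete]
        kwargs = {}
        if has_cov:
            kwargs = dict(
                age1=wide[(age, 1)], age2=wide[(age, 2)],
                sex1=wide[(sex, 1)], sex2=wide[(sex, 2)],
            )
        return cls(
            y1=wide[(phenotype, 1)].to_numpy(),
            y2=wide[(phenotype, 2)].to_numpy(),
            mz=(zyg == "MZ").to_numpy(),
            **kwargs,
        )


def _design_matrices(sample: TwinSample) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-twin mean design matrices (intercept + available covariates)."""
    cols1, cols2, names = [np.ones(sample.n_pairs)], [np.ones(sample.n_pairs)], ["intercept"]
    if sample.age1 is not None and sample.age2 is not None:
        cols1.append(sample.age1)
        cols2.append(sample.age2)
        names.append("age")
    if sample.sex1 is not None and sample.sex2 is not None:
        cols1.append(sample.sex1)
        cols2.append(sample.sex2)
        names.append("sex")
    return np.column_stack(cols1), np.column_stack(cols2), names


def ace_loglikelihood(
    a: float,
    c: float,
    e: float,
    sample: TwinSample,
    beta: np.ndarray | None = None,
) -> float:
    """Log-likelihood of path loadings (a, c, e) for a twin sample.

    Each pair contributes a bivariate-normal density with mean X @ beta per
    twin and covariance built from a2, c2, e2 with cross-twin genetic
    correlation 1 (MZ) or 0.5 (DZ).  Returns -inf for a singular
    covariance.
    """
    x1, x2, _ = _design_matrices(sample)
    if beta is None:
        beta = np.zeros(x1.shape[1])
        beta[0] = 0.5 * (sample.y1.mean() + sample.y2.mean())
    a2, c2, e2 = a * a, c * c, e * e
    v = a2 + c2 + e2
    r1 = sample.y1 - x1 @ beta
    r2 = sample.y2 - x2 @ beta
    ll = 0.0
    for is_mz, r_a in ((True, 1.0), (False, 0.5)):
        m = sample.mz == is_mz
        n = int(m.sum())
        if n == 0:
            continue
        cv = r_a * a2 + c2
        det = v * v - cv * cv
        if det <= 0 or v <= 0:
            return -np.inf
        q = (v * (r1[m] ** 2 + r2[m] ** 2) - 2 * cv * r1[m] * r2[m]).sum() / det
        ll += -n * np.log(2 * np.pi) - 0.5 * n * np.log(det) - 0.5 * q
    return float(ll)


@dataclass
class ACEResults:
    """Fitted ACE decomposition with likelihood-ratio diagnostics.

    ``a2``, ``c2``, ``e2`` are the variance components, ``proportions``
    their shares of the total variance (summing to 1 exactly), and
    ``heritability`` the genetic share -- taken from the AE submodel when
    the C component is non-significant, following the reporting convention
    of twin studies.
    """

    model: "ACEModel"
    a: float
    c: float
    e: float
    beta: np.ndarray
    beta_names: list[str]
    loglike: float
    lrt_a_p: float
    lrt_c_p: float
    ae_a2: float | None = None  # A variance of the AE submodel, if fitted
    ae_e2: float | None = None
    converged: bool = True
    alpha: float = 0.05

    @property
    def a2(self) -> float:
        return self.a**2

    @property
    def c2(self) -> float:
        return self.c**2

    @property
    def e2(self) -> float:
        return self.e**2

    @property
    def total_variance(self) -> float:
        return self.a2 + self.c2 + self.e2

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total_variance
        return {"a2": self.a2 / t, "c2": self.c2 / t, "e2": self.e2 / t}

    @property
    def c_significant(self) -> bool:
        return self.lrt_c_p < self.alpha

    @property
    def heritability_full(self) -> float:
        """Genetic share of the full ACE model, a2 / (a2 + c2 + e2)."""
        return self.a2 / self.total_variance

    @property
    def heritability(self) -> float:
        """Reported heritability.

        Follows the twin-study reporting convention: the full-model share
        a2/(a2+c2+e2), simplified to the AE submodel's a2/(a2+e2) when the
        C component is non-significant.
        """
        if not self.c_significant and self.ae_a2 is not None:
            return self.ae_a2 / (self.ae_a2 + self.ae_e2)
        return self.heritability_full

    def summary(self) -> str:
        p = self.proportions
        lines = [
            "ACE twin model (maximum likelihood)",
            "=" * 47,
            f"pairs: {self.model.sample.n_mz} MZ, {self.model.sample.n_dz} DZ",
            f"log-likelihood: {self.loglike:.3f}",
            "-" * 47,
            f"{'component':<12}{'variance':>12}{'proportion':>12}",
            f"{'A (a^2)':<12}{self.a2:>12.4f}{p['a2']:>12.3f}",
            f"{'C (c^2)':<12}{self.c2:>12.4f}{p['c2']:>12.3f}",
            f"{'E (e^2)':<12}{self.e2:>12.4f}{p['e2']:>12.3f}",
            f"{'total':<12}{self.total_variance:>12.4f}{1.0:>12.3f}",
            "-" * 47,
            f"LRT drop A: p = {self.lrt_a_p:.4g}",
            f"LRT drop C: p = {self.lrt_c_p:.4g}"
            + ("" if self.c_significant else "  (non-significant)"),
            f"heritability h2 = {self.heritability:.3f}"
            + ("" if self.c_significant else "  [AE submodel: a2/(a2+e2)]"),
        ]
        for name, b in zip(self.beta_names, self.beta):
            lines.append(f"mean {name:<10} = {b:+.4f}")
        return "\n".join(lines)


class ACEModel:
    """Maximum-likelihood ACE model for one twin phenotype.

    Parameters
    ----------
    sample : TwinSample
        Complete twin pairs with zygosity and optional age/sex covariates.
    boundary_mixture : bool
        When True, likelihood-ratio p-values for dropping a variance
        component use the conservative 50:50 chi2(0):chi2(1) mixture
        appropriate at a variance boundary instead of the plain chi2(1).
    """

    MIN_PAIRS_RECOMMENDED = 20

    def __init__(self, sample: TwinSample, boundary_mixture: bool = False):
        if sample.n_pairs == 0:
            raise ValueError("no complete twin pairs")
        if min(sample.n_mz, sample.n_dz) < self.MIN_PAIRS_RECOMMENDED:
            import warnings

            warnings.warn(
                f"fewer than {self.MIN_PAIRS_RECOMMENDED} pairs per zygosity "
                f"({sample.n_mz} MZ, {sample.n_dz} DZ); estimates may be "
                f"unstable",
                UserWarning,
                stacklevel=2,
            )
        self.sample = sample
        self.boundary_mixture = boundary_mixture
        self._x1, self._x2, self._beta_names = _design_matrices(sample)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ACEModel":
        boundary = kwargs.pop("boundary_mixture", False)
        return cls(
            TwinSample.from_dataframe(df, **kwargs),
            boundary_mixture=boundary,
        )

    # -- likelihood machinery -------------------------------------------------

    def loglike(self, params: np.ndarray, free: tuple[bool, bool, bool]) -> float:
        """Log-likelihood at packed params (loadings for free components + beta)."""
        k = sum(free)
        loadings = iter(params[:k])
        a = next(loadings) if free[0] else 0.0
        c = next(loadings) if free[1] else 0.0
        e = next(loadings) if free[2] else 0.0
        beta = params[k:]
        return ace_loglikelihood(a, c, e, self.sample, beta)

    def _fit_constrained(self, free: tuple[bool, bool, bool]) -> tuple[np.ndarray, float]:
        y = np.concatenate([self.sample.y1, self.sample.y2])
        x = np.vstack([self._x1, self._x2])
        beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid_sd = float(np.std(y - x @ beta0))
        resid_sd = max(resid_sd, 1e-6)
        best_val, best_x = np.inf, None
        # multi-start over loading configurations: boundary solutions are
        # common, so seed from several variance splits
        starts = [(0.6, 0.3, 0.7), (0.9, 0.1, 0.4), (0.1, 0.6, 0.8), (0.45, 0.45, 0.77)]
        for sa, sc, se in starts:
            full = np.array([sa, sc, se]) * resid_sd
            x0 = np.concatenate([full[list(free_idx(free))], beta0])
            res = optimize.minimize(
                lambda p: -self.loglike(p, free),
                x0,
                method="Nelder-Mead",
                options=dict(maxiter=4000, xatol=1e-8, fatol=1e-10),
            )
            if res.fun < best_val:
                best_val, best_x = res.fun, res.x
        # polish with BFGS from the best simplex solution
        res = optimize.minimize(
            lambda p: -self.loglike(p, free), best_x, method="BFGS",
            options=dict(maxiter=500),
        )
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
        if not np.isfinite(best_val):
            raise RuntimeError("ACE fit failed to reach a finite likelihood")
        return best_x, -best_val

    def _lrt_p(self, ll_full: float, ll_restricted: float) -> float:
        stat = max(0.0, 2.0 * (ll_full - ll_restricted))
        p = float(chi2.sf(stat, df=1))
        if self.boundary_mixture:
            p = 0.5 * p if stat > 0 else 1.0
        return p

    def fit(self, alpha: float = 0.05) -> ACEResults:
        """Maximize the likelihood and run the component drop tests."""
        free_ace = (True, True, True)
        params, ll_full = self._fit_constrained(free_ace)
        a, c, e = np.abs(params[0]), np.abs(params[1]), np.abs(params[2])
        beta = params[3:]
        _, ll_ce = self._fit_constrained((False, True, True))
        ae_params, ll_ae = self._fit_constrained((True, False, True))
        lrt_a_p = self._lrt_p(ll_full, ll_ce)
        lrt_c_p = self._lrt_p(ll_full, ll_ae)
        return ACEResults(
            model=self,
            a=float(a), c=float(c), e=float(e),
            beta=beta, beta_names=self._beta_names,
            loglike=ll_full,
            lrt_a_p=lrt_a_p, lrt_c_p=lrt_c_p,
            ae_a2=float(ae_params[0] ** 2),
            ae_e2=float(ae_params[1] ** 2),
            alpha=alpha,
        )


def free_idx(free: tuple[bool, bool, bool]) -> list[int]:
    return [i for i, f in enumerate(free) if f]


def falconer_h2(sample: TwinSample) -> float:
    """Falconer's rough heritability 2 * (r_MZ - r_DZ), clipped to [0, 1].

    A sanity-check companion to the maximum-likelihood decomposition:
    expected correlations under the path model are r_MZ = a2 + c2 and
    r_DZ = 0.5 * a2 + c2 (on standardized phenotypes).
    """
    if min(sample.n_mz, sample.n_dz) < 3:
        raise ValueError("need at least 3 pairs per zygosity")
    mz = sample.mz
    r_mz = pearsonr(sample.y1[mz], sample.y2[mz]).statistic
    r_dz = pearsonr(sample.y1[~mz], sample.y2[~mz]).statistic
    return float(np.clip(2.0 * (r_mz - r_dz), 0.0, 1.0))


def simulate_twins(
    a2: float,
    c2: float,
    e2: float,
    n_mz: int,
    n_dz: int,
    covariate_effects: dict[str, float] | None = None,
    age_range: tuple[float, float] = (16.5, 19.5),
    mean: float = 0.0,
    seed: int | None = None,
) -> TwinSample:
    """Draw twin pairs from the ACE path model with known components.

    Latent A is shared within MZ pairs and correlated 0.5 within DZ pairs;
    C is shared within every pair; E is independent per twin.  Ages are
    uniform over ``age_range`` (shared within a pair, as for twins), sex is
    Bernoulli(0.5) shared within a pair, and ``covariate_effects`` may add
    ``{"age": beta_age, "sex": beta_sex}`` to the mean.
    """
    if min(a2, c2, e2) < 0 or a2 + c2 + e2 <= 0:
        raise ValueError("variance components must be >= 0 with positive sum")
    rng = np.random.default_rng(seed)
    n = n_mz + n_dz
    mz = np.zeros(n, dtype=bool)
    mz[:n_mz] = True
    a_sd, c_sd, e_sd = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)

    a_shared = rng.standard_normal(n)
    a_unique1 = rng.standard_normal(n)
    a_unique2 = rng.standard_normal(n)
    # MZ: identical genetic factor; DZ: correlation 0.5
    g1 = np.where(mz, a_shared, np.sqrt(0.5) * a_shared + np.sqrt(0.5) * a_unique1)
    g2 = np.where(mz, a_shared, np.sqrt(0.5) * a_shared + np.sqrt(0.5) * a_unique2)
    c_shared = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2_ = rng.standard_normal(n)

    y1 = mean + a_sd * g1 + c_sd * c_shared + e_sd * e1
    y2 = mean + a_sd * g2 + c_sd * c_shared + e_sd * e2_

    age = rng.uniform(*age_range, size=n)
    sex = (rng.random(n) < 0.5).astype(float)
    effects = covariate_effects or {}
    y1 = y1 + effects.get("age", 0.0) * age + effects.get("sex", 0.0) * sex
    y2 = y2 + effects.get("age", 0.0) * age + effects.get("sex", 0.0) * sex
    return TwinSample(
        y1=y1, y2=y2, mz=mz, age1=age, age2=age, sex1=sex, sex2=sex
    )
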