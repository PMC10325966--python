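"""Synthetic spatial transcriptomics with controlled ligand-receptor interaction.

Each simulated gene is a latent Gaussian field over the spots, built from up
to four unit-variance components mixed by variance fractions that sum to 1:

* intrinsic  — a linear function of the paired receptor field (expression
  explained by the partner's state rather than by space);
* environment — a draw from a Gaussian process with RBF covariance on the
  coordinates (smooth tissue structure);
* interaction — the spatially weighted neighbour receptor profile
  ``W @ receptor`` (high ligand where neighbouring receptor is high: the
  signal the bivariate Moran statistic is built to detect);
* noise — white Gaussian.

Latent fields are converted to counts through a lognormal-Poisson read-out,
so the generated samples run through the exact same normalize/weights/test
pipeline as real data. Receptor genes always carry the zero-interaction
profile; ligand genes carry the configured mixture, and ligands whose
realized correlation with their receptor is negative have their sign
flipped so "interaction" always means positive co-expression.

A variance-component maximum-likelihood fit (:func:`fit_svca_like`) inverts
the generative model: given one pair, it estimates the four fractions from
data, enabling re-simulation of a fitted pair at any interaction level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

from .io import LRDatabase, LRPair, SpotSample, normalize_log
from .weights import SpatialWeights, build_rbf_weights

__all__ = [
    "SimulationConfig",
    "scaled_config",
    "simulate_null",
    "simulate_interacting",
    "simulate_mixed",
    "SvcaFit",
    "fit_svca_like",
]

#: practical spot-count bound for the dense-kernel ML fit
FIT_MAX_SPOTS = 2000


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe a modest sequencing-based slide: a 300-spot unit
    lattice, smooth tissue structure at a 2-spot length scale, spatial
    (environmental) variance 0.02 against white noise 0.98 for a gene with
    no interaction, and a lognormal-Poisson count read-out with mean
    depth 1 per gene per spot (spot-level platforms spread a few thousand
    UMIs over >15k genes, so a typical ligand or receptor transcript is
    seen in zero-to-few copies per spot). The small environmental share mirrors a typical
    non-spatially-variable gene: Moran-type tests target an exchangeability
    null, and when both partners carry strong autocorrelation at the
    analysis scale, permutation and analytic tests alike become
    anti-conservative (the Clifford-Richardson effect), which is outside
    the regime these tests are designed for. ``weights_l`` / ``weights_cutoff`` parameterize the
    interaction kernel (the same RBF weights the tests use on unit grids).
    """

    n_spots: int = 300
    grid: str = "lattice"  # or "random-uniform"
    length_scale: float = 2.0
    n_pairs: int = 500
    interaction_fraction: float = 0.0
    intrinsic_fraction: float = 0.0
    env_fraction: float = 0.02
    noise_fraction: float = 0.98
    weights_l: float = 1.2
    weights_cutoff: float = 0.2
    count_depth: float = 1.0
    dispersion: float = 0.7  # lognormal scale of the Poisson rate
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = np.array(
            [
                self.interaction_fraction,
                self.intrinsic_fraction,
                self.env_fraction,
                self.noise_fraction,
            ]
        )
        if (fracs < 0).any():
            raise ValueError("variance fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-8:
            raise ValueError(f"variance fractions sum to {fracs.sum()}, not 1")
        if not 0 <= self.interaction_fraction <= 0.99:
            raise ValueError("interaction_fraction must be in [0, 0.99]")
        if self.grid not in {"lattice", "random-uniform"}:
            raise ValueError(f"unknown grid {self.grid!r}")


def scaled_config(interaction_fraction: float, **overrides) -> SimulationConfig:
    """Config with interaction at ``f`` and the rest of the variance split
    proportionally to the zero-interaction profile (env 0.02 : noise 0.98)."""
    rest = 1.0 - interaction_fraction
    cfg = SimulationConfig(
        interaction_fraction=interaction_fraction,
        intrinsic_fraction=0.0,
        env_fraction=0.02 * rest,
        noise_fraction=0.98 * rest,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _make_coords(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_spots
    if config.grid == "lattice":
        side = int(np.ceil(np.sqrt(n)))
        xx, yy = np.meshgrid(np.arange(side), np.arange(side))
        coords = np.column_stack([xx.ravel(), yy.ravel()])[:n].astype(float)
    else:
        coords = rng.uniform(0, np.sqrt(n), size=(n, 2))
    return coords


def _gp_cholesky(coords: np.ndarray, length_scale: float) -> np.ndarray:
    K = np.exp(-cdist(coords, coords, "sqeuclidean") / (2 * length_scale**2))
    K[np.diag_indices_from(K)] += 1e-8
    return np.linalg.cholesky(K)


def _unit(v: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit population variance."""
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _counts_from_field(
    fields: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal-Poisson read-out; fields are spots x genes, unit variance."""
    s = config.dispersion
    rate = config.count_depth * np.exp(s * fields - 0.5 * s * s)
    return rng.poisson(rate).astype(float)


def _simulate(
    config: SimulationConfig,
    n_null: int,
    n_pos: int,
    receptor_field: np.ndarray | None = None,
):
    rng = np.random.default_rng(config.seed)
    coords = _make_coords(config, rng)
    n = config.n_spots
    chol = _gp_cholesky(coords, config.length_scale)
    w: SpatialWeights | None = None
    if n_pos > 0:
        w = build_rbf_weights(coords, l=config.weights_l, cutoff=config.weights_cutoff)

    n_total = n_null + n_pos
    lig_fields = np.empty((n, n_total))
    rec_fields = np.empty((n, n_total))
    interacting = np.zeros(n_total, dtype=bool)
    interacting[n_null:] = True

    # zero-interaction profile (receptors and null ligands): the configured
    # env:noise ratio renormalized to full variance
    base = config.env_fraction + config.noise_fraction
    if base > 0:
        null_env = config.env_fraction / base
        null_noise = config.noise_fraction / base
    else:
        null_env, null_noise = 0.0, 1.0

    for k in range(n_total):
        if receptor_field is not None and interacting[k]:
            rec = _unit(np.asarray(receptor_field, dtype=float))
        else:
            rec = np.sqrt(null_env) * (chol @ rng.standard_normal(n)) + np.sqrt(
                null_noise
            ) * rng.standard_normal(n)
        rec_fields[:, k] = rec

        if interacting[k]:
            parts = {
                "intrinsic": (config.intrinsic_fraction, _unit(rec)),
                "env": (
                    config.env_fraction,
                    _unit(chol @ rng.standard_normal(n)),
                ),
                "interaction": (
                    config.interaction_fraction,
                    _unit(w.dot(rec)),
                ),
                "noise": (config.noise_fraction, rng.standard_normal(n)),
            }
            lig = sum(np.sqrt(f) * comp for f, comp in parts.values())
            if np.corrcoef(lig, rec)[0, 1] < 0:
                lig = -lig  # enforce positive realized co-expression
        else:
            lig = np.sqrt(null_env) * (chol @ rng.standard_normal(n)) + np.sqrt(
                null_noise
            ) * rng.standard_normal(n)
        lig_fields[:, k] = lig

    width = max(4, len(str(n_total)))
    lig_names = [f"LG{k:0{width}d}" for k in range(n_total)]
    rec_names = [f"RC{k:0{width}d}" for k in range(n_total)]
    fields = np.concatenate([lig_fields, rec_fields], axis=1)
    counts = _counts_from_field(fields, config, rng)

    sample = SpotSample(
        spot_ids=pd.Index([f"spot{i:04d}" for i in range(n)]),
        gene_names=pd.Index(lig_names + rec_names),
        raw_counts=counts,
        coords=coords,
    )
    sample = normalize_log(sample)

    pairs = [
        LRPair(
            pair_id=f"P{k:0{width}d}",
            ligand_subunits=[lig_names[k]],
            receptor_subunits=[rec_names[k]],
            pathway=f"PW{k % 10}",
            signalling_type="secreted",
        )
        for k in range(n_total)
    ]
    db = LRDatabase(pairs=pairs, species="synthetic", version_tag="sim")

    truth = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "interacting": interacting,
            "interaction_fraction": np.where(
                interacting, config.interaction_fraction, 0.0
            ),
        }
    )
    truth.attrs["ligand_fields"] = pd.DataFrame(
        lig_fields, index=sample.spot_ids, columns=lig_names
    )
    truth.attrs["receptor_fields"] = pd.DataFrame(
        rec_fields, index=sample.spot_ids, columns=rec_names
    )
    return sample, db, truth


def simulate_null(config: SimulationConfig):
    """Zero-interaction sample: ligand and receptor fields independent.

    Returns ``(sample, db)``; every pair in the returned database is null
    by construction, so p-values over many pairs should be uniform.
    """
    if config.interaction_fraction != 0:
        raise ValueError("simulate_null requires interaction_fraction = 0")
    sample, db, _ = _simulate(config, n_null=config.n_pairs, n_pos=0)
    return sample, db


def simulate_interacting(
    config: SimulationConfig, receptor_field: np.ndarray | None = None
):
    """Sample in which every pair carries the configured interaction mixture.

    Returns ``(sample, db, truth)``. ``truth`` marks interacting pairs and
    carries the latent (pre-count) ligand/receptor fields in
    ``truth.attrs``. An explicit ``receptor_field`` (e.g. taken from real
    data) replaces the simulated receptor for every pair.
    """
    if config.interaction_fraction <= 0:
        raise ValueError("simulate_interacting requires interaction_fraction > 0")
    return _simulate(
        config, n_null=0, n_pos=config.n_pairs, receptor_field=receptor_field
    )


def simulate_mixed(config: SimulationConfig, n_null: int, n_interacting: int):
    """One sample mixing ``n_null`` null and ``n_interacting`` interacting
    pairs on shared coordinates — the standard power/ROC evaluation input."""
    if n_interacting > 0 and config.interaction_fraction <= 0:
        raise ValueError("mixed sets with positives need interaction_fraction > 0")
    cfg = replace(config, n_pairs=n_null + n_interacting)
    return _simulate(cfg, n_null=n_null, n_pos=n_interacting)


# ---------------------------------------------------------------------------
# variance-component fit
# ---------------------------------------------------------------------------


@dataclass
class SvcaFit:
    """ML variance-component estimates for one ligand against its receptor."""

    fractions: dict[str, float]
    sigma2: dict[str, float]
    loglik: float
    converged: bool
    grad_norm: float
    n_restarts: int = 3
    message: str = ""

    def rescaled_config(self, interaction_fraction: float, **overrides) -> SimulationConfig:
        """Config reproducing the fitted split with interaction rescaled."""
        others = {k: v for k, v in self.fractions.items() if k != "interaction"}
        rest = sum(others.values())
        scale = (1.0 - interaction_fraction) / rest if rest > 0 else 0.0
        return SimulationConfig(
            interaction_fraction=interaction_fraction,
            intrinsic_fraction=others["intrinsic"] * scale,
            env_fraction=others["env"] * scale,
            noise_fraction=others["noise"] * scale,
            **overrides,
        )


def _normalized_kernel(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    tr = np.trace(K)
    if tr <= 0:
        raise ValueError("kernel has non-positive trace")
    return K * (n / tr)


def fit_svca_like(
    sample: SpotSample,
    pair: LRPair,
    env_length_scale: float = 2.0,
    weights: SpatialWeights | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
) -> SvcaFit:
    """ML fit of the four variance components of a ligand's expression.

    Models the (standardized composite) ligand vector as a zero-mean
    multivariate normal with covariance

        sigma2_intr * K_intr + sigma2_env * K_env
        + sigma2_int * K_int + sigma2_noise * I,

    where K_intr is the linear kernel on the receptor subunit expression,
    K_env an RBF kernel on the coordinates, and K_int the linear kernel on
    the spatially weighted receptor profile ``W @ receptor``. Kernels are
    trace-normalized, so fitted sigma2 values are comparable and their
    shares are the variance fractions. Optimized over log-variances with
    L-BFGS-B from ``n_restarts`` seeded starting points.
    """
    if sample.expr is None:
        raise ValueError("sample has no normalized expression; run normalize_log")
    n = sample.n_spots
    if n > FIT_MAX_SPOTS:
        raise ValueError(f"dense ML fit is limited to {FIT_MAX_SPOTS} spots")
    rng = np.random.default_rng(seed)

    from .global_stats import composite_expression  # local import avoids cycle

    x = composite_expression(sample, pair.ligand_subunits)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant ligand expression")
    x = (x - x.mean()) / sd

    Yr = np.column_stack([sample.expr_vector(g) for g in pair.receptor_subunits])
    Yr = (Yr - Yr.mean(axis=0)) / np.where(Yr.std(axis=0) > 0, Yr.std(axis=0), 1.0)

    if weights is None:
        weights = build_rbf_weights(sample.coords, l=1.2, cutoff=0.2)
    Z = weights.dot(Yr)
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)

    kernels = {
        "intrinsic": _normalized_kernel(Yr @ Yr.T),
        "env": _normalized_kernel(
            np.exp(-cdist(sample.coords, sample.coords, "sqeuclidean")
                   / (2 * env_length_scale**2))
        ),
        "interaction": _normalized_kernel(Z @ Z.T),
        "noise": np.eye(n),
    }
    names = list(kernels)
    Ks = [kernels[k] for k in names]

    def nll(theta: np.ndarray) -> float:
        sig = np.exp(theta)
        cov = sum(s * K for s, K in zip(sig, Ks))
        jitter = 1e-10
        for _ in range(8):
            try:
                cho = linalg.cho_factor(
                    cov + jitter * np.eye(n), lower=True, check_finite=False
                )
                break
            except linalg.LinAlgError:
                jitter *= 100
        else:
            return 1e10
        alpha = linalg.cho_solve(cho, x, check_finite=False)
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        return 0.5 * (logdet + x @ alpha + n * np.log(2 * np.pi))

    best = None
    for _ in range(max(1, n_restarts)):
        theta0 = rng.normal(-1.0, 1.0, size=len(Ks))
        res = optimize.minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            bounds=[(-12.0, 6.0)] * len(Ks),
            options={"ftol": tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    sig = np.exp(best.x)
    total = sig.sum()
    grad_norm = float(np.linalg.norm(best.jac)) if best.jac is not None else np.nan
    if not best.success:
        warnings.warn(
            f"variance-component fit did not fully converge "
            f"(gradient norm {grad_norm:.2e}): {best.message}"
        )
    return SvcaFit(
        fractions={k: float(s / total) for k, s in zip(names, sig)},
        sigma2={k: float(s) for k, s in zip(names, sig)},
        loglik=float(-best.fun),
        converged=bool(best.success),
        grad_norm=grad_norm,
        n_restarts=n_restarts,
        message=str(best.message),
    )
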