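"""Independent oracle implementations used by the test suite.

Everything here is deliberately written from first principles (plain
arithmetic on reflectance values, direct eigendecompositions, Monte Carlo
over the generative equations) and never calls the package code paths it
is used to check.
"""

import math

import numpy as np

from leafspec.spectra import GRID, GRID_MIN
from leafspec.simulate import DEFAULT_FEATURES, PIGMENTS


def rho(refl: np.ndarray, lam: int) -> float:
    return float(refl[lam - GRID_MIN])


def brute_force_indices(refl: np.ndarray) -> dict:
    """The eight index formulas evaluated literally."""
    out = {}
    out["NDVI"] = (rho(refl, 800) - rho(refl, 670)) / (
        rho(refl, 800) + rho(refl, 670))
    out["MCARI"] = (
        (rho(refl, 700) - rho(refl, 670))
        - 0.2 * (rho(refl, 700) - rho(refl, 550))
    ) * (rho(refl, 700) / rho(refl, 670))
    out["PRI"] = (rho(refl, 570) - rho(refl, 530)) / (
        rho(refl, 570) + rho(refl, 530))
    out["PSRI"] = (rho(refl, 680) - rho(refl, 500)) / rho(refl, 750)
    l1510, l1680 = math.log(1 / rho(refl, 1510)), math.log(1 / rho(refl, 1680))
    out["NDNI"] = (l1510 - l1680) / (l1510 + l1680)
    l1754 = math.log(1 / rho(refl, 1754))
    out["NDLI"] = (l1754 - l1680) / (l1754 + l1680)
    out["NDWI"] = (rho(refl, 860) - rho(refl, 1240)) / (
        rho(refl, 860) + rho(refl, 1240))
    out["NPQI"] = (rho(refl, 415) - rho(refl, 435)) / (
        rho(refl, 415) + rho(refl, 435))
    return out


def pca_eigen_oracle(X: np.ndarray) -> np.ndarray:
    """Explained-variance fractions from a direct eigendecomposition of the
    sample covariance of the centred matrix."""
    Xc = X - X.mean(axis=0)
    evals = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))
    evals = np.sort(evals)[::-1]
    return evals / evals.sum()


# ---------------------------------------------------------------------------
# generative-model band arithmetic (for effect-injection oracles)
# ---------------------------------------------------------------------------

def _band_absorbance(lam: float) -> dict:
    out = {}
    for pigment, feats in DEFAULT_FEATURES.items():
        out[pigment] = sum(
            f.strength * math.exp(-0.5 * ((lam - f.center) / f.width) ** 2)
            for f in feats
        )
    return out


def _plateau_at(lam: float, cfg) -> float:
    shape = math.exp(-0.5 * ((lam - cfg.plateau_center) / cfg.plateau_width) ** 2)
    return cfg.plateau_amplitude * ((1 - cfg.plateau_floor) * shape
                                    + cfg.plateau_floor)


def mc_true_psri_effect(cfg, n_draws: int = 200_000, seed: int = 987) -> float:
    """Monte-Carlo estimate of the marginal eCO2 - aCO2 expected-PSRI
    difference implied by a simulator configuration, computed directly from
    the generative equations at the three PSRI bands."""
    rng = np.random.default_rng(seed)
    conc_sd = math.sqrt(cfg.sigma_tree**2 + cfg.sigma_tree_date**2
                        + cfg.sigma_leaf**2)
    amp_sd = math.sqrt(cfg.plateau_sigma_tree**2
                       + cfg.plateau_sigma_tree_date**2
                       + cfg.plateau_sigma_leaf**2)
    bands = (680, 500, 750)
    absorb = {lam: _band_absorbance(lam) for lam in bands}
    means = {}
    for trt in ("aCO2", "eCO2"):
        base = cfg.mean_concentrations(trt)
        logc = np.log([base[p] for p in PIGMENTS]) + rng.normal(
            0.0, conc_sd, size=(n_draws, len(PIGMENTS)))
        conc = np.exp(logc)
        amp_mult = np.exp(rng.normal(0.0, amp_sd, size=n_draws))
        if trt == "eCO2":
            amp_mult = amp_mult * cfg.eco2_plateau_multiplier
        R = {}
        for lam in bands:
            a = sum(conc[:, i] * absorb[lam][p]
                    for i, p in enumerate(PIGMENTS))
            r = _plateau_at(lam, cfg) * amp_mult * np.exp(-a)
            if cfg.noise_sd > 0:
                r = r + rng.normal(0.0, cfg.noise_sd, size=n_draws)
            R[lam] = np.clip(r, 0.0, 1.0)
        means[trt] = float(np.mean((R[680] - R[500]) / R[750]))
    return means["eCO2"] - means["aCO2"]


def delta_method_psri_variances(cfg) -> dict:
    """PSRI-scale variance components implied by small log-scale hierarchy
    SDs: var_level ~= sigma_level^2 * ||grad||^2 with grad the gradient of
    PSRI in the per-pigment log concentrations, plus the white-noise
    contribution at the three bands for the residual level."""
    base = cfg.mean_concentrations("aCO2")
    logc0 = np.log([base[p] for p in PIGMENTS])

    def psri_of(logc):
        conc = np.exp(logc)
        R = {}
        for lam in (680, 500, 750):
            a = sum(conc[i] * _band_absorbance(lam)[p]
                    for i, p in enumerate(PIGMENTS))
            R[lam] = _plateau_at(lam, cfg) * math.exp(-a)
        return (R[680] - R[500]) / R[750]

    eps = 1e-5
    grad = np.array([
        (psri_of(logc0 + eps * np.eye(4)[i])
         - psri_of(logc0 - eps * np.eye(4)[i])) / (2 * eps)
        for i in range(4)
    ])
    g2 = float(grad @ grad)
    r750 = _plateau_at(750, cfg) * math.exp(-sum(
        np.exp(logc0)[i] * _band_absorbance(750)[p]
        for i, p in enumerate(PIGMENTS)))
    noise_var = cfg.noise_sd**2 * (2 + psri_of(logc0) ** 2) / r750**2
    return {
        "tree": cfg.sigma_tree**2 * g2,
        "tree_date": cfg.sigma_tree_date**2 * g2,
        "residual": cfg.sigma_leaf**2 * g2 + noise_var,
    }
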