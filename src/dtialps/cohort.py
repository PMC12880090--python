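"""Synthetic two-group longitudinal stroke cohorts.

Emulates a randomized trial in which ischemic-stroke patients receive two
weeks of either high-frequency (HF, excitatory, infarcted-hemisphere M1) or
low-frequency (LF, inhibitory, intact-hemisphere M1) rTMS, with bilateral
ALPS indices and upper-limb clinical scales measured at baseline (BL) and
follow-up (FU).

Construction, per subject:

* hemispheric baseline ALPS values are bivariate normal with a configurable
  inter-hemisphere correlation; the total-cerebral value is their mean;
* per-hemisphere ALPS change rates (% per day) are drawn from the group
  distributions, and follow-up ALPS is obtained by inverting the
  change-rate definition: ``FU = BL * (1 + rate/100 * days)``;
* a Gaussian copula couples the non-stimulated-hemisphere change rate to
  the WMFT improvement (target correlation ``rho_wmft``) and the
  stimulated-hemisphere rate to the FMA improvement (``rho_fma``);
* clinical scales are rounded, range-clipped draws respecting each scale's
  bounds (the scales are ordinal/bounded).

With ``empirical=True`` the drawn ALPS baselines and change rates are
affinely standardized so their *sample* mean/SD per group equal the
specified parameters exactly (the mvrnorm ``empirical=TRUE`` idiom).  The
affine map preserves the copula correlations.  This mode turns published
group-summary tables into a concrete cohort whose summary statistics
reproduce them; leave it off for calibration studies, where genuine
sampling variability is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "ScaleParams", "generate_cohort", "COHORT_SCHEMA_VERSION"]

COHORT_SCHEMA_VERSION = "1"

GROUPS = ("HF", "LF")
REGIONS = ("total", "stimulated", "non_stimulated")
SCALES = (
    "nihss", "brunnstrom", "fma", "mas", "ashworth", "swmt", "wmft", "adl", "qol",
)

#: cohort CSV column order (schema version 1)
COHORT_COLUMNS = (
    ["id", "group", "age", "sex", "bmi", "lymphocytes", "onset_days",
     "infarct_side", "fu_days"]
    + [f"alps_{r}_{t}" for r in ("total", "stim", "nonstim") for t in ("bl", "fu")]
    + [f"{s}_{t}" for s in SCALES for t in ("bl", "fu")]
)


@dataclass(frozen=True)
class ScaleParams:
    """One clinical scale: per-group baseline distribution, shared
    improvement distribution, admissible range and rounding."""

    bl: dict[str, tuple[float, float]]  # group -> (mean, sd) or (median, sigma)
    delta: tuple[float, float]  # (mean, sd) of FU - BL
    lo: float
    hi: float
    decimals: int = 0
    bl_dist: str = "normal"  # normal | lognormal


def _default_scales() -> dict[str, ScaleParams]:
    return {
        # stroke severity falls with recovery
        "nihss": ScaleParams({"HF": (7.6, 2.6), "LF": (7.8, 2.8)}, (-3.0, 2.0), 0, 42),
        "brunnstrom": ScaleParams(
            {"HF": (2.5, 1.3), "LF": (3.0, 1.0)}, (1.0, 0.8), 1, 6
        ),
        "fma": ScaleParams({"HF": (8.0, 6.0), "LF": (9.0, 6.5)}, (8.0, 6.0), 0, 66),
        "mas": ScaleParams({"HF": (2.0, 2.5), "LF": (1.0, 1.5)}, (0.0, 1.0), 0, 54),
        "ashworth": ScaleParams(
            {"HF": (0.6, 0.8), "LF": (1.1, 1.0)}, (0.0, 0.5), 0, 4
        ),
        "swmt": ScaleParams({"HF": (2.2, 1.3), "LF": (2.2, 1.3)}, (0.0, 0.7), 1, 6),
        "wmft": ScaleParams(
            {"HF": (3.0, 1.3), "LF": (5.0, 1.1)}, (8.0, 6.0), 0, 75,
            bl_dist="lognormal",
        ),
        "adl": ScaleParams(
            {"HF": (55.7, 22.6), "LF": (50.3, 16.7)}, (10.0, 8.0), 0, 100
        ),
        "qol": ScaleParams(
            {"HF": (158.0, 30.0), "LF": (150.0, 29.0)}, (10.0, 10.0), 0, 300
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated trial; defaults follow the two-group
    stroke cohort summaries (n = 17 HF / 18 LF)."""

    n_hf: int = 17
    n_lf: int = 18
    # per-group, per-hemisphere baseline ALPS (mean, sd)
    baseline_alps: dict = field(default_factory=lambda: {
        "HF": {"stimulated": (1.235, 0.117), "non_stimulated": (1.209, 0.102)},
        "LF": {"stimulated": (1.235, 0.108), "non_stimulated": (1.190, 0.106)},
    })
    #: correlation between the two hemispheres' baseline indices
    baseline_corr: float = 0.5
    # per-group, per-hemisphere ALPS change rate in % per day (mean, sd)
    change_rate_effect: dict = field(default_factory=lambda: {
        "HF": {"stimulated": (-0.013, 0.199), "non_stimulated": (-0.108, 0.178)},
        "LF": {"stimulated": (0.041, 0.197), "non_stimulated": (0.027, 0.124)},
    })
    #: correlation between the two hemispheres' change rates
    rate_corr: float = 0.5
    fu_interval: dict = field(default_factory=lambda: {
        "HF": (14.0, 3.0), "LF": (13.0, 3.0),
    })
    #: target corr(non-stimulated change rate, WMFT improvement)
    rho_wmft: float = -0.42
    #: target corr(stimulated change rate, FMA improvement)
    rho_fma: float = 0.35
    covariates: dict = field(default_factory=lambda: {
        "age": {"HF": (60.8, 6.5), "LF": (57.2, 6.2)},
        "male_fraction": {"HF": 11 / 17, "LF": 13 / 18},
        "bmi": {"HF": (23.0, 3.9), "LF": (24.8, 3.0)},
        "lymphocytes": {"HF": (1.6, 0.5), "LF": (1.6, 0.6)},
        # (median days, log-sd): onset delays are right-skewed
        "onset_days": {"HF": (10.0, 0.55), "LF": (12.5, 1.0)},
    })
    scales: dict = field(default_factory=_default_scales)
    seed: int = 0
    #: standardize sample moments of ALPS baselines/rates to the parameters
    empirical: bool = False

    def __post_init__(self) -> None:
        if self.n_hf < 2 or self.n_lf < 2:
            raise ValueError("need at least 2 subjects per group")
        for rho, name in (
            (self.rho_wmft, "rho_wmft"),
            (self.rho_fma, "rho_fma"),
            (self.baseline_corr, "baseline_corr"),
            (self.rate_corr, "rate_corr"),
        ):
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"{name}={rho} outside [-1, 1]")
        for grp in GROUPS:
            for store, label in (
                (self.baseline_alps, "baseline_alps"),
                (self.change_rate_effect, "change_rate_effect"),
            ):
                for hemi, (_, sd) in store[grp].items():
                    if sd < 0:
                        raise ValueError(f"{label}[{grp}][{hemi}] sd < 0")
            if self.fu_interval[grp][1] < 0:
                raise ValueError(f"fu_interval[{grp}] sd < 0")
        self.latent_correlation()  # validates feasibility

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of (rate_stim, rate_nonstim, dWMFT, dFMA).

        Raises if the requested correlations are jointly infeasible (the
        matrix is not positive definite), naming the offending parameters.
        """
        c = np.array([
            [1.0, self.rate_corr, 0.0, self.rho_fma],
            [self.rate_corr, 1.0, self.rho_wmft, 0.0],
            [0.0, self.rho_wmft, 1.0, 0.0],
            [self.rho_fma, 0.0, 0.0, 1.0],
        ])
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            raise ValueError(
                "infeasible correlation structure: rate_corr="
                f"{self.rate_corr}, rho_wmft={self.rho_wmft}, "
                f"rho_fma={self.rho_fma} admit no joint Gaussian copula"
            ) from None
        return c


def _standardize(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affine map making the sample mean/SD (ddof=1) exactly (mean, sd)."""
    s = x.std(ddof=1)
    if s == 0:
        return np.full_like(x, mean)
    return mean + sd * (x - x.mean()) / s


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject; bit-identical given the same spec (incl. seed)."""
    chol = np.linalg.cholesky(spec.latent_correlation())
    ss = np.random.SeedSequence(spec.seed)
    rngs = {g: np.random.default_rng(s) for g, s in zip(GROUPS, ss.spawn(2))}

    frames = []
    offset = 0
    for grp, n in (("HF", spec.n_hf), ("LF", spec.n_lf)):
        rng = rngs[grp]
        cov = spec.covariates

        age = np.clip(rng.normal(*cov["age"][grp], n), 18, 80).round(1)
        n_male = int(round(cov["male_fraction"][grp] * n))
        sex = rng.permutation(["M"] * n_male + ["F"] * (n - n_male))
        bmi = np.clip(rng.normal(*cov["bmi"][grp], n), 14, 45).round(1)
        lymph = np.clip(rng.normal(*cov["lymphocytes"][grp], n), 0.2, 4.0).round(1)
        med, lsd = cov["onset_days"][grp]
        onset = np.clip(rng.lognormal(np.log(med), lsd, n), 1, 180).round(0)
        infarct = rng.choice(["left", "right"], n)
        fu_mu, fu_sd = spec.fu_interval[grp]
        fu_days = np.clip(np.round(rng.normal(fu_mu, fu_sd, n)), 7, None)

        # baseline ALPS: bivariate normal over (stimulated, non-stimulated)
        zb = rng.standard_normal((n, 2))
        zb[:, 1] = spec.baseline_corr * zb[:, 0] + np.sqrt(
            1 - spec.baseline_corr**2
        ) * zb[:, 1]
        (m_s, s_s) = spec.baseline_alps[grp]["stimulated"]
        (m_n, s_n) = spec.baseline_alps[grp]["non_stimulated"]
        bl_stim = m_s + s_s * zb[:, 0]
        bl_nonstim = m_n + s_n * zb[:, 1]

        # copula latent: (rate_stim, rate_nonstim, dWMFT, dFMA)
        z = rng.standard_normal((n, 4)) @ chol.T
        (rm_s, rs_s) = spec.change_rate_effect[grp]["stimulated"]
        (rm_n, rs_n) = spec.change_rate_effect[grp]["non_stimulated"]
        rate_stim = rm_s + rs_s * z[:, 0]
        rate_nonstim = rm_n + rs_n * z[:, 1]

        if spec.empirical:
            bl_stim = _standardize(bl_stim, m_s, s_s)
            bl_nonstim = _standardize(bl_nonstim, m_n, s_n)
            rate_stim = _standardize(rate_stim, rm_s, rs_s)
            rate_nonstim = _standardize(rate_nonstim, rm_n, rs_n)

        bl_stim = np.maximum(bl_stim, 0.5)
        bl_nonstim = np.maximum(bl_nonstim, 0.5)
        # invert the change-rate definition to place the follow-up values
        fu_stim = bl_stim * (1 + rate_stim / 100.0 * fu_days)
        fu_nonstim = bl_nonstim * (1 + rate_nonstim / 100.0 * fu_days)

        row = {
            "id": [f"S{offset + i + 1:03d}" for i in range(n)],
            "group": grp,
            "age": age, "sex": sex, "bmi": bmi, "lymphocytes": lymph,
            "onset_days": onset, "infarct_side": infarct, "fu_days": fu_days,
            "alps_total_bl": 0.5 * (bl_stim + bl_nonstim),
            "alps_total_fu": 0.5 * (fu_stim + fu_nonstim),
            "alps_stim_bl": bl_stim, "alps_stim_fu": fu_stim,
            "alps_nonstim_bl": bl_nonstim, "alps_nonstim_fu": fu_nonstim,
        }

        for name, sp in spec.scales.items():
            p1, p2 = sp.bl[grp]
            if sp.bl_dist == "lognormal":
                bl = rng.lognormal(np.log(max(p1, 1e-9)), p2, n)
            else:
                bl = rng.normal(p1, p2, n)
            bl = np.clip(np.round(bl, sp.decimals), sp.lo, sp.hi)
            dm, dsd = sp.delta
            if name == "wmft":
                delta = dm + dsd * z[:, 2]
            elif name == "fma":
                delta = dm + dsd * z[:, 3]
            else:
                delta = rng.normal(dm, dsd, n)
            fu = np.clip(np.round(bl + delta, sp.decimals), sp.lo, sp.hi)
            row[f"{name}_bl"] = bl
            row[f"{name}_fu"] = fu

        frames.append(pd.DataFrame(row))
        offset += n

    df = pd.concat(frames, ignore_index=True)
    return df[COHORT_COLUMNS]
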