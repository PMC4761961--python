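"""One-site isothermal titration calorimetry: simulation, fitting, audits.

An ITC experiment titrates RNA (syringe, concentration ``X_s``) into the
protein cell (volume ``V0``, concentration ``M0``) and integrates the heat of
each injection, normalized per mole of injectant.  For a single class of
``n`` independent sites with association constant ``Ka``, total concentrations
after injection ``i`` follow the standard displaced-volume dilution,

    M_i = M0 * f^i,   X_i = X_s * (1 - f^i),   f = 1 - v/V0,

the bound-complex concentration is the closed-form root of the 1:1 mass
balance quadratic with total site concentration ``n * M_i``,

    C_i = ((S + X + 1/Ka) - sqrt((S + X + 1/Ka)^2 - 4 S X)) / 2,  S = n * M_i,

and the normalized heat of injection ``i`` is the newly formed complex in the
cell over the moles injected,

    q_i = V0 * dH * (C_i - f * C_{i-1}) / (X_s * v)   [kcal/mol of injectant].

In the stoichiometric (very strong binding) regime this gives exactly
``q_i = dH`` before saturation and 0 after — the expected staircase limit.

Fitting is a statsmodels-style pair: :class:`OneSiteBindingModel` wraps an
experiment and its forward model; ``fit()`` returns
:class:`OneSiteBindingResults` carrying estimates (n, Ka, dH), asymptotic
standard errors, derived dG and TdS, convergence diagnostics and a
``summary()`` table.  Derived quantities use dG = -R T ln Ka with
R = 1.987e-3 kcal/(mol K) and TdS = dH - dG.

``audit_table`` checks printed thermodynamic tables for internal consistency:
dG vs dH - TdS, dG vs -RT ln Ka, and sign anomalies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._resources import data_path

__all__ = [
    "R_KCAL",
    "ItcExperiment",
    "ThermoFit",
    "OneSiteBindingModel",
    "OneSiteBindingResults",
    "simulate_isotherm",
    "fit_one_site",
    "derive_thermodynamics",
    "audit_table",
    "load_table4",
    "read_isotherm_csv",
    "write_isotherm_csv",
]

#: gas constant, kcal/(mol K)
R_KCAL = 1.987e-3


@dataclass(frozen=True)
class ItcExperiment:
    """Injection schedule, cell/syringe contents and (optionally) measured heats.

    Concentrations in M, volumes in L, temperature in K; ``heats`` are the
    integrated injection heats in kcal per mole of injectant.
    """

    cell_conc: float
    syringe_conc: float
    n_injections: int
    injection_volume: float = 10e-6
    cell_volume: float = 1.4e-3
    temperature: float = 298.15
    heats: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.injection_volume <= 0 or self.cell_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.n_injections < 1:
            raise ValueError("need at least one injection")
        if self.heats is not None and len(self.heats) != self.n_injections:
            raise ValueError(
                f"{len(self.heats)} heats for {self.n_injections} injections"
            )

    @property
    def dilution_factor(self) -> float:
        return 1.0 - self.injection_volume / self.cell_volume

    def total_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """(macromolecule, titrant) total concentrations after each injection."""
        i = np.arange(1, self.n_injections + 1)
        f = self.dilution_factor**i
        return self.cell_conc * f, self.syringe_conc * (1.0 - f)

    @property
    def molar_ratios(self) -> np.ndarray:
        m, x = self.total_concentrations()
        return x / m


@dataclass(frozen=True)
class ThermoFit:
    """One-site thermodynamic parameter set (with derived dG and TdS)."""

    n: float
    ka: float
    dh: float
    dg: float
    tds: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("ka must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def derive_thermodynamics(n: float, ka: float, dh: float, T: float = 298.15) -> ThermoFit:
    """dG = -R T ln Ka, TdS = dH - dG (so dG + TdS == dH identically)."""
    if ka <= 0:
        raise ValueError("ka must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    dg = -R_KCAL * T * math.log(ka)
    return ThermoFit(n=n, ka=ka, dh=dh, dg=dg, tds=dh - dg, temperature=T)


def _bound_complex(site_tot: np.ndarray, x_tot: np.ndarray, ka: float) -> np.ndarray:
    """Closed-form root of the 1:1 binding quadratic (always the physical root)."""
    b = site_tot + x_tot + 1.0 / ka
    disc = b * b - 4.0 * site_tot * x_tot
    # disc = (S-X)^2 + 2(S+X)/Ka + 1/Ka^2 > 0 by construction
    if np.any(disc < 0):
        raise ArithmeticError("negative discriminant in binding quadratic")
    return 0.5 * (b - np.sqrt(disc))


def predicted_heats(n: float, ka: float, dh: float, design: ItcExperiment) -> np.ndarray:
    """Noise-free injection heats (kcal per mole of injectant) for a parameter set."""
    m_tot, x_tot = design.total_concentrations()
    c = _bound_complex(n * m_tot, x_tot, ka)
    f = design.dilution_factor
    c_prev = np.concatenate(([0.0], c[:-1]))
    moles_injected = design.syringe_conc * design.injection_volume
    return design.cell_volume * dh * (c - f * c_prev) / moles_injected


def simulate_isotherm(
    truth: ThermoFit,
    design: ItcExperiment,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ItcExperiment:
    """Synthetic isotherm: forward model plus additive Gaussian noise (kcal/mol).

    Deterministic given the seed; ``noise_sd=0`` returns the exact forward model.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    q = predicted_heats(truth.n, truth.ka, truth.dh, design)
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        q = q + rng.normal(0.0, noise_sd, size=q.size)
    return replace(design, heats=tuple(float(v) for v in q))


class OneSiteBindingModel:
    """One-site binding isotherm model for an ITC experiment with measured heats.

    Parameters are (n, Ka, dH); Ka is optimized on a log scale for
    conditioning.  Construct from an :class:`ItcExperiment` (or via
    :meth:`from_dataframe`) and call :meth:`fit`.
    """

    def __init__(self, experiment: ItcExperiment):
        if experiment.heats is None:
            raise ValueError("experiment carries no measured heats")
        if experiment.n_injections < 6:
            raise ValueError("need at least 6 injections to fit three parameters")
        ratios = experiment.molar_ratios
        if np.any(np.diff(ratios) <= 0):
            raise ValueError("molar-ratio schedule must be strictly increasing")
        heats = np.asarray(experiment.heats, dtype=float)
        if np.allclose(heats, 0.0, atol=1e-9):
            raise ValueError("flat isotherm (all heats ~ 0): nothing to fit")
        self.experiment = experiment
        self.endog = heats

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cell_conc: float,
        syringe_conc: float,
        cell_volume: float = 1.4e-3,
        temperature: float = 298.15,
    ) -> "OneSiteBindingModel":
        """Build from an isotherm table with columns volume_uL and heat_kcal_per_mol."""
        idx = df["injection_index"].to_numpy(dtype=float)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("injection schedule must be in strictly increasing order")
        vols = df["volume_uL"].to_numpy(dtype=float)
        if vols.size and not np.allclose(vols, vols[0]):
            raise ValueError("only constant injection volumes are supported")
        exp = ItcExperiment(
            cell_conc=cell_conc,
            syringe_conc=syringe_conc,
            n_injections=len(df),
            injection_volume=float(vols[0]) * 1e-6,
            cell_volume=cell_volume,
            temperature=temperature,
            heats=tuple(df["heat_kcal_per_mol"].astype(float)),
        )
        return cls(exp)

    # -- initialization heuristics ------------------------------------------
    def _start_params(self) -> tuple[float, float, float]:
        q = self.endog
        ratios = self.experiment.molar_ratios
        dh0 = float(q[:2].mean())
        if dh0 == 0.0:
            dh0 = float(q[np.argmax(np.abs(q))])
        moles = self.experiment.syringe_conc * self.experiment.injection_volume
        cum = np.cumsum(q * moles)
        half = 0.5 * cum[-1]
        idx = int(np.argmin(np.abs(cum - half)))
        n0 = float(np.clip(ratios[idx], 0.05, 10.0))
        ka0 = 10.0 / (n0 * self.experiment.cell_conc)  # c ~ 10 guess
        return n0, ka0, dh0

    def predict(self, n: float, ka: float, dh: float) -> np.ndarray:
        return predicted_heats(n, ka, dh, self.experiment)

    def fit(
        self,
        start: tuple[float, float, float] | None = None,
        max_iter: int = 2000,
    ) -> "OneSiteBindingResults":
        n0, ka0, dh0 = start if start is not None else self._start_params()

        def residuals(theta):
            n, log_ka, dh = theta
            return self.predict(n, math.exp(log_ka), dh) - self.endog

        sol = least_squares(
            residuals,
            x0=[n0, math.log(ka0), dh0],
            bounds=([1e-4, math.log(1.0), -np.inf], [100.0, math.log(1e18), np.inf]),
            max_nfev=max_iter,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if not sol.success:
            raise RuntimeError(
                f"one-site fit did not converge: {sol.message} "
                f"(nfev={sol.nfev}, cost={sol.cost:.3g})"
            )
        n_hat, log_ka_hat, dh_hat = sol.x
        dof = max(self.endog.size - 3, 1)
        sigma2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = sigma2 * np.linalg.inv(jtj)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
            bse = np.full(3, np.nan)
        # delta method: se(Ka) = Ka * se(log Ka)
        ka_hat = math.exp(log_ka_hat)
        return OneSiteBindingResults(
            model=self,
            n=float(n_hat),
            ka=float(ka_hat),
            dh=float(dh_hat),
            bse_n=float(bse[0]),
            bse_log_ka=float(bse[1]),
            bse_ka=float(ka_hat * bse[1]),
            bse_dh=float(bse[2]),
            n_iterations=int(sol.nfev),
            residual_norm=float(np.sqrt(2.0 * sol.cost)),
            converged=bool(sol.success),
        )


@dataclass(frozen=True)
class OneSiteBindingResults:
    """Estimates, uncertainties and diagnostics from a one-site ITC fit."""

    model: OneSiteBindingModel
    n: float
    ka: float
    dh: float
    bse_n: float
    bse_log_ka: float
    bse_ka: float
    bse_dh: float
    n_iterations: int
    residual_norm: float
    converged: bool

    @property
    def temperature(self) -> float:
        return self.model.experiment.temperature

    @property
    def thermo(self) -> ThermoFit:
        return derive_thermodynamics(self.n, self.ka, self.dh, self.temperature)

    @property
    def dg(self) -> float:
        return self.thermo.dg

    @property
    def tds(self) -> float:
        return self.thermo.tds

    @property
    def c_value(self) -> float:
        """Wiseman c = n * Ka * [M]cell, the sigmoidicity/identifiability index."""
        return self.n * self.ka * self.model.experiment.cell_conc

    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.n, self.ka, self.dh)

    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues()

    def summary(self) -> str:
        lines = [
            "One-site ITC binding fit",
            "=" * 48,
            f"injections: {self.model.experiment.n_injections}"
            f"   T = {self.temperature:.2f} K   c = {self.c_value:.1f}",
            f"n    = {self.n:10.4f} +/- {self.bse_n:.4f} sites",
            f"Ka   = {self.ka:10.4g} +/- {self.bse_ka:.3g} 1/M",
            f"dH   = {self.dh:10.3f} +/- {self.bse_dh:.3f} kcal/mol",
            f"dG   = {self.dg:10.3f} kcal/mol   (-RT ln Ka)",
            f"TdS  = {self.tds:10.3f} kcal/mol   (dH - dG)",
            f"residual norm = {self.residual_norm:.4g} kcal/mol"
            f"   (nfev {self.n_iterations})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "ka_per_M": self.ka,
            "dh_kcal_mol": self.dh,
            "dg_kcal_mol": self.dg,
            "tds_kcal_mol": self.tds,
            "temperature_K": self.temperature,
            "bse": {"n": self.bse_n, "ka": self.bse_ka, "dh": self.bse_dh},
            "c_value": self.c_value,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "residual_norm": self.residual_norm,
        }

    def plot(self, ax=None):
        """Molar-ratio vs heat plot with the fitted curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ratios = self.model.experiment.molar_ratios
        ax.plot(ratios, self.model.endog, "o", label="integrated heats")
        ax.plot(ratios, self.fittedvalues(), "-", label="one-site fit")
        ax.set_xlabel("molar ratio [titrant]/[macromolecule]")
        ax.set_ylabel("kcal per mole of injectant")
        ax.legend()
        return ax


def fit_one_site(experiment: ItcExperiment) -> OneSiteBindingResults:
    """Convenience wrapper: build the model and fit with default settings."""
    return OneSiteBindingModel(experiment).fit()


# ---------------------------------------------------------------------------
# printed-table audit


def audit_table(
    rows: pd.DataFrame | Sequence[dict],
    tolerance: float = 0.05,
) -> dict:
    """Internal-consistency audit of printed (n, Ka, dH, TdS, dG) rows.

    Per row: ``residual_identity = dG - (dH - TdS)`` and
    ``residual_lnka = dG - (-RT ln Ka)``; rows are flagged when a residual
    exceeds ``tolerance`` (kcal/mol) and when dG has an unphysical positive
    sign for Ka > 1 (sign anomaly).
    """
    df = pd.DataFrame(rows)
    out_rows = []
    for r in df.itertuples(index=False):
        dg_from_identity = r.dh_kcal_mol - r.tds_kcal_mol
        dg_from_ka = -R_KCAL * 298.15 * math.log(r.ka_per_M)
        res1 = r.dg_kcal_mol - dg_from_identity
        res2 = r.dg_kcal_mol - dg_from_ka
        sign_anomaly = bool(r.dg_kcal_mol > 0 and r.ka_per_M > 1)
        out_rows.append(
            {
                "name": r.name,
                "residual_identity": round(float(res1), 4),
                "residual_lnka": round(float(res2), 4),
                "identity_flag": bool(abs(res1) > tolerance),
                "lnka_flag": bool(abs(res2) > tolerance),
                "sign_anomaly": sign_anomaly,
            }
        )
    return {
        "tolerance_kcal_mol": tolerance,
        "rows": out_rows,
        "n_rows": len(out_rows),
        "n_identity_flagged": sum(r["identity_flag"] for r in out_rows),
        "n_lnka_flagged": sum(r["lnka_flag"] for r in out_rows),
        "n_sign_anomalies": sum(r["sign_anomaly"] for r in out_rows),
    }


def load_table4() -> pd.DataFrame:
    """Packaged fixture of the printed ITC parameter table (17 rows; the
    candidate whose synthesis failed is absent, as printed)."""
    return pd.read_csv(data_path("table4_thermo.tsv"), sep="\t")


def read_isotherm_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"injection_index", "volume_uL", "heat_kcal_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isotherm CSV missing columns: {sorted(missing)}")
    return df


def write_isotherm_csv(exp: ItcExperiment, path: str | Path) -> None:
    if exp.heats is None:
        raise ValueError("experiment has no heats to write")
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, exp.n_injections + 1),
            "volume_uL": exp.injection_volume * 1e6,
            "heat_kcal_per_mol": exp.heats,
        }
    )
    df.to_csv(path, index=False)
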