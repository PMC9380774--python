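"""Global exponential-plateau fitting of cleavage time courses.

Endonucleolytic cleavage of a labeled RNA substrate is followed on gels as
the fraction of substrate consumed over time.  The percentage cleaved
follows an exponential plateau,

    Y(t) = Y_max - (Y_max - Y_0) * exp(-k t),

where ``Y_max`` (plateau, % of initial substrate) and ``Y_0`` (value at
t=0) are shared across all enzyme complexes fitted jointly ("globally
restrained") while each complex gets its own rate constant ``k``
(min^-1).  The half-time — the time at which half of the maximal cleaved
fraction is reached, Y(t50) = Y_max/2 — has the closed form

    t50 = ln( 2 (Y_max - Y_0) / Y_max ) / k,

defined only while Y_0 < Y_max/2.  Uncertainties come from a seeded
case-resampling bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

K_LOWER_BOUND = 1e-6  # min^-1


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

class TimeCourseSet:
    """Tidy replicate time courses for one or more enzyme complexes.

    Wraps a DataFrame with columns ``complex, replicate, time_min`` and
    either raw band intensities (``intensity``, ``intensity_t0``) or a
    precomputed ``percent_cleaved`` column.
    """

    REQUIRED = ("complex", "replicate", "time_min")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"time-course table missing columns {missing}")
        frame = frame.copy()
        if "percent_cleaved" not in frame.columns:
            if not {"intensity", "intensity_t0"} <= set(frame.columns):
                raise ValueError(
                    "need either percent_cleaved or intensity + intensity_t0"
                )
            frame["percent_cleaved"] = percent_cleaved(
                frame["intensity"].to_numpy(), frame["intensity_t0"].to_numpy()
            )
        if (frame["time_min"] < 0).any():
            raise ValueError("timepoints must be non-negative")
        self.frame = frame.sort_values(["complex", "replicate", "time_min"]).reset_index(
            drop=True
        )

    @property
    def complexes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.frame["complex"]:
            seen.setdefault(c, None)
        return list(seen)

    def of(self, complex_name: str) -> pd.DataFrame:
        return self.frame[self.frame["complex"] == complex_name]

    def __add__(self, other: "TimeCourseSet") -> "TimeCourseSet":
        return TimeCourseSet(pd.concat([self.frame, other.frame], ignore_index=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourseSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def percent_cleaved(intensity: np.ndarray, intensity_t0: np.ndarray) -> np.ndarray:
    """Percent of substrate cleaved relative to the initial band intensity.

    ``Y = (1 - substrate_t / substrate_t0) * 100``; values may fall outside
    [0, 100] through measurement noise and are deliberately not clipped.
    """
    intensity_t0 = np.asarray(intensity_t0, dtype=float)
    if (intensity_t0 <= 0).any():
        raise ValueError("initial substrate intensity must be positive")
    return (1.0 - np.asarray(intensity, dtype=float) / intensity_t0) * 100.0


def plateau_model(t: np.ndarray, y_max: float, y_0: float, k: float) -> np.ndarray:
    return y_max - (y_max - y_0) * np.exp(-k * np.asarray(t, dtype=float))


def t50(y_max: float, y_0: float, k: float) -> float:
    """Closed-form half-time of the exponential-plateau model (min).

    Solves ``Y(t50) = Y_max / 2``.  Raises when ``Y_0 >= Y_max/2`` (the
    half-maximum is already passed at t=0) or parameters are invalid.
    """
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    if y_max <= 0 or y_0 >= y_max:
        raise ValueError("require 0 < Y_max and Y_0 < Y_max")
    if y_0 >= y_max / 2:
        raise ValueError("Y_0 >= Y_max/2: half-maximum already passed at t=0")
    return math.log(2.0 * (y_max - y_0) / y_max) / k


def rate_from_t50(y_max: float, y_0: float, t_50: float) -> float:
    """Invert the half-time expression for the rate constant k."""
    if t_50 <= 0:
        raise ValueError("t50 must be positive")
    return math.log(2.0 * (y_max - y_0) / y_max) / t_50


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class CleavageKineticsResults:
    """Fitted global plateau parameters, per-complex rates and half-times."""

    y_max: float
    y_0: float
    rates: pd.Series               # k per complex, min^-1
    r_squared: pd.Series
    converged: bool
    n_obs: int
    model: "CleavageKinetics"
    ci: pd.DataFrame | None = None  # per-parameter bootstrap CIs

    @property
    def t50(self) -> pd.Series:
        out = {}
        for name, k in self.rates.items():
            try:
                out[name] = t50(self.y_max, self.y_0, k)
            except ValueError:
                out[name] = np.nan
        s = pd.Series(out, name="t50_min")
        return s

    def predict(self, complex_name: str, t: np.ndarray) -> np.ndarray:
        return plateau_model(t, self.y_max, self.y_0, self.rates[complex_name])

    def bootstrap_ci(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        ci: float = 0.95,
        method: str = "residual",
    ) -> pd.DataFrame:
        """Percentile bootstrap CIs for k and t50 per complex.

        ``method='residual'`` (default) resamples leverage-inflated fit
        residuals pooled within each complex; this is well calibrated at
        the two-to-five replicates typical of gel time courses.
        ``method='case'`` resamples replicates with replacement within each
        timepoint (with the sqrt(n/(n-1)) finite-sample inflation); with
        very few replicates per timepoint it runs slightly narrow.
        Complexes with a single replicate always use residual resampling
        (warned when case resampling was requested).
        """
        if n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if method not in ("residual", "case"):
            raise ValueError(f"unknown bootstrap method {method!r}")
        rng = np.random.default_rng(seed)
        model = self.model
        boot_k = {name: [] for name in self.rates.index}
        boot_t50 = {name: [] for name in self.rates.index}
        boot_ymax, boot_y0 = [], []

        frames = {name: model.data.of(name) for name in self.rates.index}
        single_rep = {
            name: df.groupby("time_min")["replicate"].nunique().max() < 2
            for name, df in frames.items()
        }
        if method == "case" and any(single_rep.values()):
            warnings.warn(
                "single-replicate complex(es); falling back to residual resampling",
                stacklevel=2,
            )
        # params attributable to one complex: its k plus a share of Y_max/Y_0
        p_eff = 1.0 + 2.0 / len(frames)

        for _ in range(n_boot):
            pieces = []
            for name, df in frames.items():
                if method == "residual" or single_rep[name]:
                    pred = plateau_model(
                        df["time_min"].to_numpy(), self.y_max, self.y_0, self.rates[name]
                    )
                    resid = df["percent_cleaved"].to_numpy() - pred
                    inflate = np.sqrt(resid.size / max(resid.size - p_eff, 1.0))
                    resampled = df.copy()
                    resampled["percent_cleaved"] = pred + inflate * rng.choice(
                        resid, size=resid.size, replace=True
                    )
                    pieces.append(resampled)
                else:
                    parts = []
                    for _, grp in df.groupby("time_min"):
                        n = len(grp)
                        idx = rng.integers(0, n, size=n)
                        resampled = grp.iloc[idx].copy()
                        # finite-sample correction: resampling n replicates
                        # understates the variance by (n-1)/n
                        center = grp["percent_cleaved"].mean()
                        resampled["percent_cleaved"] = center + (
                            resampled["percent_cleaved"] - center
                        ) * np.sqrt(n / max(n - 1, 1))
                        parts.append(resampled)
                    pieces.append(pd.concat(parts))
            boot_data = TimeCourseSet(pd.concat(pieces, ignore_index=True))
            try:
                res = CleavageKinetics(boot_data).fit()
            except RuntimeError:
                continue
            boot_ymax.append(res.y_max)
            boot_y0.append(res.y_0)
            for name in self.rates.index:
                boot_k[name].append(res.rates[name])
                try:
                    boot_t50[name].append(t50(res.y_max, res.y_0, res.rates[name]))
                except ValueError:
                    boot_t50[name].append(np.nan)

        lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
        rows = []
        rows.append(("Y_max", *np.percentile(boot_ymax, [lo, hi])))
        rows.append(("Y_0", *np.percentile(boot_y0, [lo, hi])))
        for name in self.rates.index:
            rows.append((f"k[{name}]", *np.percentile(boot_k[name], [lo, hi])))
            rows.append(
                (f"t50[{name}]", *np.nanpercentile(boot_t50[name], [lo, hi]))
            )
        out = pd.DataFrame(rows, columns=["parameter", "ci_low", "ci_high"]).set_index(
            "parameter"
        )
        self.ci = out
        return out

    def summary(self) -> str:
        lines = [
            "Exponential-plateau cleavage kinetics (global fit)",
            "=" * 50,
            f"shared Y_max: {self.y_max:8.3f} %",
            f"shared Y_0:   {self.y_0:8.4f} %",
            f"observations: {self.n_obs}   converged: {self.converged}",
            "-" * 50,
            f"{'complex':<16}{'k (min^-1)':>12}{'t50 (min)':>12}{'R^2':>8}",
        ]
        t = self.t50
        for name in self.rates.index:
            lines.append(
                f"{name:<16}{self.rates[name]:>12.5f}{t[name]:>12.3g}"
                f"{self.r_squared[name]:>8.3f}"
            )
        if self.ci is not None:
            lines.append("-" * 50)
            lines.append("bootstrap 95% CIs:")
            for p, row in self.ci.iterrows():
                lines.append(f"  {p:<14} [{row.ci_low:.4g}, {row.ci_high:.4g}]")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k_per_min": self.rates,
                "t50_min": self.t50,
                "r_squared": self.r_squared,
                "y_max": self.y_max,
                "y_0": self.y_0,
            }
        )

    def plot(self, path=None, ax=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        for name in self.rates.index:
            df = self.model.data.of(name)
            ax.plot(df["time_min"], df["percent_cleaved"], "o", ms=3, alpha=0.6)
            tt = np.linspace(0, df["time_min"].max(), 200)
            ax.plot(tt, self.predict(name, tt), label=name)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("substrate cleaved (%)")
        ax.legend(frameon=False, fontsize=8)
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight")
        return ax


class CleavageKinetics:
    """Model object for the globally restrained exponential-plateau fit.

    All complexes share ``Y_max`` and ``Y_0``; each contributes its own
    rate constant.  ``fit`` is nonlinear least squares on the pooled
    percentage-cleaved observations.
    """

    def __init__(self, data: TimeCourseSet) -> None:
        for name in data.complexes:
            if data.of(name)["time_min"].nunique() < 3:
                raise ValueError(
                    f"complex {name!r} has fewer than 3 distinct timepoints"
                )
        self.data = data

    def _initial_guess(self) -> np.ndarray:
        df = self.data.frame
        y0 = df[df["time_min"] == df["time_min"].min()]["percent_cleaved"].mean()
        ymax = df[df["time_min"] == df["time_min"].max()]["percent_cleaved"].mean()
        if ymax <= y0:
            ymax = y0 + 1.0
        ks = []
        for name in self.data.complexes:
            sub = self.data.of(name)
            y = sub["percent_cleaved"].to_numpy()
            t = sub["time_min"].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.log(np.maximum(ymax * 1.05 - y, 1e-6))
            ok = np.isfinite(z) & (t > 0)
            if ok.sum() >= 2:
                slope = np.polyfit(t[ok], z[ok], 1)[0]
                ks.append(max(-slope, 1e-3))
            else:
                ks.append(0.1)
        return np.array([ymax, max(y0, 0.0), *ks])

    def fit(self) -> CleavageKineticsResults:
        names = self.data.complexes
        df = self.data.frame
        t = df["time_min"].to_numpy()
        y = df["percent_cleaved"].to_numpy()
        idx = np.array([names.index(c) for c in df["complex"]])

        def residuals(theta: np.ndarray) -> np.ndarray:
            ymax, y0 = theta[0], theta[1]
            k = theta[2:][idx]
            return plateau_model_vec(t, ymax, y0, k) - y

        x0 = self._initial_guess()
        lower = np.array([1e-3, -100.0] + [K_LOWER_BOUND] * len(names))
        upper = np.array([200.0, 100.0] + [np.inf] * len(names))
        x0 = np.clip(x0, lower + 1e-9, None)
        sol = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
        if not sol.success:
            raise RuntimeError(
                f"plateau fit did not converge: {sol.message}; best iterate {sol.x}"
            )
        ymax, y0 = float(sol.x[0]), float(sol.x[1])
        rates = pd.Series(sol.x[2:], index=pd.Index(names, name="complex"), name="k")
        if (rates <= K_LOWER_BOUND * 1.001).any() or (ymax - y0) < 1e-6 * max(1.0, ymax):
            flat = rates.index[rates <= K_LOWER_BOUND * 1.001].tolist() or list(rates.index)
            warnings.warn(
                f"rate constant at lower bound or unidentifiable for {flat}; "
                "data may be flat",
                stacklevel=2,
            )
        r2 = {}
        for name in names:
            sub = self.data.of(name)
            pred = plateau_model(sub["time_min"].to_numpy(), ymax, y0, rates[name])
            resid = sub["percent_cleaved"].to_numpy() - pred
            sst = np.sum(
                (sub["percent_cleaved"] - sub["percent_cleaved"].mean()) ** 2
            )
            r2[name] = 1.0 - float(np.sum(resid**2) / sst) if sst > 0 else np.nan
        return CleavageKineticsResults(
            y_max=ymax,
            y_0=y0,
            rates=rates,
            r_squared=pd.Series(r2, name="r_squared"),
            converged=bool(sol.success),
            n_obs=len(df),
            model=self,
        )


def plateau_model_vec(t: np.ndarray, y_max: float, y_0: float, k: np.ndarray) -> np.ndarray:
    return y_max - (y_max - y_0) * np.exp(-k * t)


def fit_global_plateau(data: TimeCourseSet) -> CleavageKineticsResults:
    """Functional wrapper around :class:`CleavageKinetics`."""
    return CleavageKinetics(data).fit()


# ---------------------------------------------------------------------------
# packaged RNA substrates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstrateSequence:
    """A labeled in vitro RNA substrate with its polyadenylation signal."""

    id: str
    sequence: str
    labels: tuple[str, ...] = ()
    pas_motif: str = "AAGAA"

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGU"):
            raise ValueError("substrate sequence must be RNA (A/C/G/U)")
        if self.pas_motif not in self.sequence:
            raise ValueError(f"PAS motif {self.pas_motif} absent from {self.id}")

    @property
    def pas_location(self) -> int:
        return self.sequence.find(self.pas_motif)

    def __len__(self) -> int:
        return len(self.sequence)


_SUBSTRATE_LABELS = {
    "pcCYC1": ("5'FAM",),
    "CYC1": ("5'FAM", "3'Alexa647"),
}


def load_substrates() -> dict[str, SubstrateSequence]:
    """The packaged CYC1-derived substrates (precleaved and full-length)."""
    from Bio import SeqIO

    path = Path(__file__).parent / "data" / "cyc1_substrates.fasta"
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = SubstrateSequence(
            rec.id, str(rec.seq), _SUBSTRATE_LABELS.get(rec.id, ())
        )
    return out
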