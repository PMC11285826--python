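"""Model parameters in reduced units.

Every quantity in the simulation is expressed in reduced units: lengths in
the cell diameter ``sigma``, time in ``tau``, energy in ``eps`` (the depth
scale of the cell-cell pair potential) and nutrient concentration in the
bulk value ``C0``.  :class:`ModelParams` collects every constant of the
model in one validated record and is the single source of defaults for the
driver, the CLI and the tests.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

__all__ = ["ModelParams", "SIGMA_W_DEFAULT"]

#: Range parameter of the substrate repulsion, (2/5)^(1/6) sigma.
SIGMA_W_DEFAULT: float = (2.0 / 5.0) ** (1.0 / 6.0)


@dataclasses.dataclass
class ModelParams:
    """All reduced-unit constants of the biofilm model.

    Parameters
    ----------
    L0_star
        Initial (and post-division) aspect ratio ``L* = L/sigma + 1``.
    veff
        Fraction of nutrient uptake converted into elongation.
    mu_max
        Maximum uptake rate per unit aspect-ratio length [1/tau].
    Ks_star
        Monod half-saturation concentration relative to the bulk, Ks/C0.
    DN_star
        Nutrient diffusion coefficient relative to D0, DN/D0.
    D0_star
        Reference cell diffusion coefficient [sigma^2/tau].
    eps_BB, eps_rep, eps_att
        Cell-cell, substrate-repulsion and substrate-adhesion strengths [eps].
    sigma_w
        Range parameter of the substrate repulsion [sigma].
    kBT
        Thermal energy [eps]; the overdamped mobility is D/kBT.
    dt
        Brownian-dynamics timestep [tau].
    grid_h
        Edge of the cubic nutrient compartments [sigma].
    C0
        Bulk nutrient concentration (the concentration unit).
    force_cap
        Magnitude cap applied to any single force contribution [eps/sigma].
    nutrient_stride
        Number of BD steps between nutrient-field updates.
    snapshot_factor
        Multiplicative biomass spacing between measurement snapshots.
    max_biomass, max_time
        Stop criteria for a single run.
    n_replicates
        Default number of independent runs in replicate mode.
    seed
        Base RNG seed.
    """

    L0_star: float = 2.6
    veff: float = 0.9
    mu_max: float = 1.1
    Ks_star: float = 10.0
    DN_star: float = 1000.0
    D0_star: float = 0.1
    eps_BB: float = 1.0
    eps_rep: float = 100.0
    eps_att: float = 20.0
    sigma_w: float = SIGMA_W_DEFAULT
    kBT: float = 1.0
    dt: float = 1e-4
    grid_h: float = 10.85
    C0: float = 1.0
    force_cap: float = 1e4
    nutrient_stride: int = 1
    snapshot_factor: float = 1.15
    max_biomass: float = 1000.0
    max_time: float = math.inf
    n_replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.grid_h <= 0:
            raise ValueError("grid_h must be positive")
        if self.D0_star <= 0:
            raise ValueError("D0_star must be positive")
        if self.L0_star < 1.0:
            raise ValueError("L0_star must be >= 1 (aspect ratio convention)")
        if self.C0 <= 0:
            raise ValueError("C0 must be positive")
        if self.Ks_star < 0 or self.DN_star <= 0:
            raise ValueError("Ks_star must be >= 0 and DN_star > 0")
        if self.kBT <= 0 or self.veff < 0 or self.mu_max < 0:
            raise ValueError("kBT must be > 0; veff and mu_max must be >= 0")
        if self.nutrient_stride < 1:
            raise ValueError("nutrient_stride must be >= 1")
        if self.snapshot_factor <= 1.0:
            raise ValueError("snapshot_factor must exceed 1")

    # ---- derived constants -------------------------------------------------

    @property
    def D0(self) -> float:
        """Reference diffusion coefficient [sigma^2/tau]."""
        return self.D0_star

    @property
    def DN(self) -> float:
        """Nutrient diffusion coefficient DN = DN* . D0 [sigma^2/tau]."""
        return self.DN_star * self.D0

    @property
    def Ks(self) -> float:
        """Half-saturation concentration [C0 units]."""
        return self.Ks_star * self.C0

    @property
    def d_rep(self) -> float:
        """Activation range of the substrate repulsion, (2/5)^(1/6) sigma_w."""
        return (2.0 / 5.0) ** (1.0 / 6.0) * self.sigma_w

    @property
    def d_c(self) -> float:
        """Activation range of the substrate adhesion, sigma_w + 0.5 sigma."""
        return self.sigma_w + 0.5

    @property
    def max_Lstar(self) -> float:
        """Division threshold 2 L0*."""
        return 2.0 * self.L0_star

    # ---- flat key=value config files --------------------------------------

    _FLOAT_FIELDS = (
        "L0_star", "veff", "mu_max", "Ks_star", "DN_star", "D0_star",
        "eps_BB", "eps_rep", "eps_att", "sigma_w", "kBT", "dt", "grid_h",
        "C0", "force_cap", "snapshot_factor", "max_biomass", "max_time",
    )
    _INT_FIELDS = ("nutrient_stride", "n_replicates", "seed")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Read parameters from a flat ``key = value`` text file.

        Unknown keys are rejected; missing keys take the defaults above.
        Lines starting with ``#`` and blank lines are ignored.
        """
        kwargs: dict[str, object] = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: cannot parse {raw!r}")
                key, val = parts
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            if key in cls._INT_FIELDS:
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        """Write the parameters as a flat ``key = value`` text file."""
        lines = ["# biofilmsim parameters (reduced units)"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")
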