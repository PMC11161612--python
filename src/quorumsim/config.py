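"""Flat key=value run configuration shared by the CLI and scenario export.

The config file format is deliberately minimal: one ``key = value`` pair per
line, ``#`` comments, no sections.  Unknown keys are rejected by name so a
typo never silently falls back to a default.  CLI flags override file
values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Tuple

from .diffusion_model import ColonyParameters
from .feasibility import DEFAULT_THRESHOLD, ThresholdConfig, calibrate_threshold
from .growth_dynamics import GrowthParameters

__all__ = ["RunConfig", "parse_config", "scenario_to_config"]


@dataclass
class RunConfig:
    """All tunables of a simulator run, in user-facing units.

    Colony block: ``production_rate`` (molecules/cell-s), ``cell_density``
    (cells/mL), ``radius_mm``, ``diffusion`` (cm^2/s), ``cell_width_um``.
    Threshold: either a fixed ``threshold_nM`` or a calibration reference
    (``calibrate_radius_mm``, ``calibrate_diffusion``) reusing the colony's
    P, n and Ws.  Sweep: ``sweep_param`` in {D, P, n, R} plus a
    comma-separated ``sweep_grid``.  Growth block mirrors
    :class:`~quorumsim.growth_dynamics.GrowthParameters`.
    """

    production_rate: Optional[float] = None
    cell_density: Optional[float] = None
    radius_mm: Optional[float] = None
    diffusion: Optional[float] = None
    cell_width_um: float = 1.0

    threshold_nM: Optional[float] = None
    calibrate_radius_mm: Optional[float] = None
    calibrate_diffusion: Optional[float] = None

    sweep_param: Optional[str] = None
    sweep_grid: Optional[Tuple[float, ...]] = None

    theta_in: Optional[float] = None
    theta0: Optional[float] = None
    beta0: Optional[float] = None
    alpha: Optional[float] = None
    gamma: Optional[float] = None
    ks: Optional[float] = None
    k_dec: Optional[float] = None
    mu_max: Optional[float] = None
    t_end: Optional[float] = None
    dt_report: Optional[float] = None

    coupling_mode: str = "density_and_radius"

    def colony(self) -> ColonyParameters:
        missing = [
            k
            for k in ("production_rate", "cell_density", "radius_mm", "diffusion")
            if getattr(self, k) is None
        ]
        if missing:
            raise ValueError(f"missing colony parameter(s): {', '.join(missing)}")
        return ColonyParameters.from_lab_units(
            production_rate=self.production_rate,
            cell_density_per_ml=self.cell_density,
            colony_radius_mm=self.radius_mm,
            diffusion_coefficient=self.diffusion,
            cell_width_um=self.cell_width_um,
        )

    def threshold(self) -> ThresholdConfig:
        if self.calibrate_radius_mm is not None:
            if self.calibrate_diffusion is None:
                raise ValueError(
                    "calibrate_radius_mm given without calibrate_diffusion"
                )
            ref = ColonyParameters.from_lab_units(
                production_rate=self.production_rate,
                cell_density_per_ml=self.cell_density,
                colony_radius_mm=self.calibrate_radius_mm,
                diffusion_coefficient=self.calibrate_diffusion,
                cell_width_um=self.cell_width_um,
            )
            return calibrate_threshold(ref)
        if self.threshold_nM is not None:
            return ThresholdConfig(self.threshold_nM, note="config")
        return DEFAULT_THRESHOLD

    def growth(self) -> GrowthParameters:
        defaults = GrowthParameters()
        mapping = {
            "theta_in": "substrate_in",
            "theta0": "initial_substrate",
            "beta0": "initial_cells",
            "alpha": "flow_rate",
            "gamma": "yield_coefficient",
            "ks": "half_saturation",
            "k_dec": "decay_rate",
            "mu_max": "mu_max",
            "t_end": "t_end",
            "dt_report": "dt_report",
        }
        kwargs = {
            gp_field: getattr(self, key)
            for key, gp_field in mapping.items()
            if getattr(self, key) is not None
        }
        if not kwargs:
            return defaults
        from dataclasses import replace

        return replace(defaults, **kwargs)


_STRING_KEYS = {"sweep_param", "coupling_mode"}
_GRID_KEYS = {"sweep_grid"}
_VALID_KEYS = {f.name for f in fields(RunConfig)}


def parse_config(text: str, base: Optional[RunConfig] = None) -> RunConfig:
    """Parse flat ``key = value`` text into a :class:`RunConfig`.

    Raises ``ValueError`` naming any unknown key (with its line number).
    """
    cfg = base if base is not None else RunConfig()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _VALID_KEYS:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
        if key in _STRING_KEYS:
            setattr(cfg, key, value)
        elif key in _GRID_KEYS:
            try:
                grid = tuple(float(v) for v in value.split(",") if v.strip())
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad grid {value!r}") from exc
            setattr(cfg, key, grid)
        else:
            try:
                setattr(cfg, key, float(value))
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: key {key!r} needs a number, got {value!r}"
                ) from exc
    return cfg


def scenario_to_config(scenario) -> str:
    """Serialize a packaged scenario to the config-file format.

    Round-trips through :func:`parse_config`: re-running the exported config
    reproduces the scenario's outputs bit for bit.
    """
    from .units import cm_to_mm, cm_to_um

    lines = [f"# scenario: {scenario.name}", f"# {scenario.citation}"]
    if scenario.colony is not None:
        c = scenario.colony
        lines += [
            f"production_rate = {c.production_rate!r}",
            f"cell_density = {c.cell_density!r}",
            f"radius_mm = {cm_to_mm(c.colony_radius)!r}",
            f"diffusion = {c.diffusion_coefficient!r}",
            f"cell_width_um = {cm_to_um(c.cell_width)!r}",
        ]
    if scenario.threshold == "calibrated" and scenario.calibration is not None:
        ref = scenario.calibration
        lines += [
            f"calibrate_radius_mm = {cm_to_mm(ref.colony_radius)!r}",
            f"calibrate_diffusion = {ref.diffusion_coefficient!r}",
        ]
    elif isinstance(scenario.threshold, ThresholdConfig):
        lines.append(f"threshold_nM = {scenario.threshold.threshold_nM!r}")
    if scenario.sweep is not None:
        param, grid = scenario.sweep
        lines.append(f"sweep_param = {param}")
        lines.append("sweep_grid = " + ",".join(repr(v) for v in grid))
    if scenario.growth:
        _, gp = scenario.growth[0]
        lines += [
            f"theta_in = {gp.substrate_in!r}",
            f"theta0 = {gp.initial_substrate!r}",
            f"beta0 = {gp.initial_cells!r}",
            f"alpha = {gp.flow_rate!r}",
            f"gamma = {gp.yield_coefficient!r}",
            f"ks = {gp.half_saturation!r}",
            f"k_dec = {gp.decay_rate!r}",
            f"mu_max = {gp.mu_max!r}",
            f"t_end = {gp.t_end!r}",
            f"dt_report = {gp.dt_report!r}",
        ]
        lines.append(f"coupling_mode = {scenario.coupling_mode}")
    return "\n".join(lines) + "\n"
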