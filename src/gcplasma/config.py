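"""Simulation configuration, affinity model and perturbation schedule.

The simulation is parameterized by a flat :class:`SimConfig` plus a
:class:`PerturbationSchedule` of timed interventions (reporter labeling,
GC ablation, PC depletion, egress blockade, targeted antigen delivery).
Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

import yaml

#: canonical affinity-enhancing heavy-chain hotspot substitutions of the
#: NP-specific IGHV1-72 response, with IMGT-style 1-based codon positions.
HOTSPOT_MUTATIONS = ("W33L", "K59R", "Y99G")
HOTSPOT_POSITIONS = {"W33L": 33, "K59R": 59, "Y99G": 99}

#: germline V labels used by the simulator.  IGHV1-72 is the designated
#: high-affinity-capable heavy germline (the NP hapten system analog);
#: IGHV1-53 stands in for lower-affinity heavy rearrangements.
HIGH_AFFINITY_GERMLINE = "IGHV1-72"
#: graded continuum of lower baseline affinities, as polyclonal
#: anti-hapten repertoires have
LOW_AFFINITY_GERMLINES = ("IGHV5-17", "IGHV9-3", "IGHV1-53")
LIGHT_GERMLINE = "IGLV1"

PERTURBATION_KINDS = frozenset(
    {
        "tamoxifen_s1pr2",
        "tamoxifen_blimp1",
        "doxycycline",
        "anti_CD40L",
        "anti_IL21R",
        "TACI_Ig",
        "FTY720",
        "DEC_OVA",
    }
)


class ConfigError(ValueError):
    """Raised when a configuration field is out of range or unknown."""


@dataclass(frozen=True)
class AffinityModel:
    """Multiplicative genotype -> affinity map.

    Affinity is a dimensionless association-constant scale: the germline
    baseline ``a0`` times the product of the factors of all acquired
    non-lethal mutations.  Only designated hotspot substitutions carry
    factors > 1; every other (neutral) mutation has factor 1 and lethal
    mutations kill the cell at mutation time.
    """

    base_affinity_by_germline: dict[str, float] = field(
        default_factory=lambda: {
            HIGH_AFFINITY_GERMLINE: 10.0,
            "IGHV5-17": 5.0,
            "IGHV9-3": 2.5,
            "IGHV1-53": 1.0,
        }
    )
    mutation_effects: dict[str, float] = field(
        default_factory=lambda: {"W33L": 10.0, "K59R": 2.0, "Y99G": 2.0}
    )
    lethal_fraction: float = 0.3
    key_site_probability: float = 0.25
    high_affinity_germline: str = HIGH_AFFINITY_GERMLINE

    def __post_init__(self) -> None:
        for g, a0 in self.base_affinity_by_germline.items():
            if a0 <= 0:
                raise ConfigError(f"base_affinity_by_germline[{g!r}] must be > 0, got {a0}")
        for m, f in self.mutation_effects.items():
            if f <= 0:
                raise ConfigError(f"mutation_effects[{m!r}] must be > 0, got {f}")
        if not 0.0 <= self.lethal_fraction <= 1.0:
            raise ConfigError(f"lethal_fraction must be in [0, 1], got {self.lethal_fraction}")
        if not 0.0 <= self.key_site_probability <= 1.0:
            raise ConfigError(
                f"key_site_probability must be in [0, 1], got {self.key_site_probability}"
            )
        if self.lethal_fraction + self.key_site_probability > 1.0:
            raise ConfigError(
                "lethal_fraction + key_site_probability must be <= 1, got "
                f"{self.lethal_fraction + self.key_site_probability}"
            )
        if self.high_affinity_germline not in self.base_affinity_by_germline:
            raise ConfigError(
                f"high_affinity_germline {self.high_affinity_germline!r} has no base affinity"
            )


@dataclass(frozen=True, order=True)
class PerturbationEvent:
    """One timed intervention: ``(time_h, kind, params)``."""

    time_h: float
    kind: str
    params: tuple[tuple[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ConfigError(f"perturbation time must be >= 0, got {self.time_h}")
        if self.kind not in PERTURBATION_KINDS:
            raise ConfigError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "DEC_OVA":
            dose = dict(self.params).get("dose")
            if dose is None or dose < 0:
                raise ConfigError("DEC_OVA requires params with dose >= 0")

    @property
    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)


@dataclass(frozen=True)
class PerturbationSchedule:
    events: tuple[PerturbationEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(sorted(self.events)))

    @staticmethod
    def of(*events: tuple) -> "PerturbationSchedule":
        """Build from ``(time_h, kind)`` or ``(time_h, kind, {params})`` tuples."""
        evs = []
        for ev in events:
            if len(ev) == 2:
                t, kind = ev
                params: tuple = ()
            else:
                t, kind, p = ev
                params = tuple(sorted(p.items()))
            evs.append(PerturbationEvent(float(t), kind, params))
        return PerturbationSchedule(tuple(evs))


# fields validated as probabilities (per step or per event)
_PROB_FIELDS = (
    "fraction_high_affinity_germline",
    "p_prepc",
    "shm_rate",
    "pc_division_prob",
    "pc_death",
    "gc_death",
    "cd40l_gc_death",
    "taci_pc_death",
    "egress_prob",
    "pc_resident_prob",
)
# fields validated as nonnegative rates / scales
_NONNEG_FIELDS = (
    "antigen_level",
    "tfh_capacity",
    "help_cap",
    "capture_k",
    "hill",
    "beta",
    "alpha",
    "alpha_pc",
    "reentry_half_help",
    "secretion_rate",
    "il21_burst",
    "anti_il21r_factor",
    "dec_help_coef",
    "dec_duration_h",
    "ligand_low",
    "ligand_high",
)


@dataclass(frozen=True)
class SimConfig:
    """All tunable parameters of one simulated lymph node ("one mouse").

    Rates that are probabilities are per 6-h step unless suffixed otherwise;
    affinity and help are in arbitrary units.  See docs/methods.md for the
    rationale behind each default.
    """

    # founding
    founder_count: int = 400
    fraction_high_affinity_germline: float = 0.3
    # light-zone selection
    antigen_level: float = 1.0
    tfh_capacity: float = 500.0  # total help units distributed per step
    capture_k: float = 4.0  # half-saturation affinity of antigen capture
    hill: float = 1.0
    beta: float = 1.0  # help -> Myc slope
    help_cap: float = 0.8  # max help one cell can absorb per LZ visit (0 = no cap)
    alpha: float = 0.5  # Myc -> mean division-burst slope (DZ)
    alpha_pc: float = 10.0  # Myc -> mean division-burst slope (PC maturation)
    n_max: int = 8  # hard cap on a division burst
    reentry_half_help: float = 0.02  # help at which DZ re-entry probability = 1/2
    p_prepc: float = 0.05  # affinity-independent prePC export per LZ visit
    prepc_maturation_steps: int = 1  # LZ exit -> secreting PC within a step
    # dark-zone hypermutation
    shm_rate: float = 0.3  # per daughter cell per division
    # plasma cells
    pc_division_prob: float = 0.8  # chance of executing each pending division per step
    pc_divisions_per_step: int = 1
    pc_death: float = 0.05  # per step (~0.2/day)
    gc_death: float = 0.0  # baseline DZ death per step
    secretion_rate: float = 1.0  # antibody units per PC per step
    egress_prob: float = 0.65  # per step, idle non-resident PCs; off under FTY720
    pc_resident_prob: float = 0.015  # chance a divided PC settles in the medulla
    il21_burst: float = 1.5  # IL-21 multiplier on the PC burst mean
    # perturbation strengths
    cd40l_gc_death: float = 0.35  # per-step GC death under anti-CD40L
    taci_pc_death: float = 0.5  # per-step PC death under TACI-Ig
    anti_il21r_factor: float = 0.5  # burst multiplier under anti-IL21R
    dec_help_coef: float = 0.03  # extra help per unit DEC-OVA dose, added per LZ cell
    dec_duration_h: float = 24.0
    # division-dilution label
    label_l0: float = 1.0
    mch_lo_frac: float = 0.125  # lo gate: label <= L0/8 (>= 3 divisions)
    mch_hi_frac: float = 0.5  # hi gate: label > L0/2 (<= 1 division)
    # serum
    serum_bins: int = 32
    serum_decades: float = 6.0
    ligand_low: float = 0.01  # sparsely haptenated carrier (NP7 analog)
    ligand_high: float = 0.04  # densely haptenated carrier (NP28 analog)
    # clock
    dt_hours: float = 6.0
    duration_days: float = 14.0
    seed: int = 0
    # perturbations + affinity model
    perturbations: PerturbationSchedule = field(default_factory=PerturbationSchedule)
    affinity: AffinityModel = field(default_factory=AffinityModel)

    def __post_init__(self) -> None:
        if self.founder_count < 0:
            raise ConfigError(f"founder_count must be >= 0, got {self.founder_count}")
        if self.n_max < 0:
            raise ConfigError(f"n_max must be >= 0, got {self.n_max}")
        if self.pc_divisions_per_step < 0:
            raise ConfigError(
                f"pc_divisions_per_step must be >= 0, got {self.pc_divisions_per_step}"
            )
        if self.prepc_maturation_steps < 1:
            raise ConfigError(
                f"prepc_maturation_steps must be >= 1, got {self.prepc_maturation_steps}"
            )
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.dt_hours <= 0:
            raise ConfigError(f"dt_hours must be > 0, got {self.dt_hours}")
        if self.duration_days < 0:
            raise ConfigError(f"duration_days must be >= 0, got {self.duration_days}")
        if self.label_l0 <= 0:
            raise ConfigError(f"label_l0 must be > 0, got {self.label_l0}")
        if self.serum_bins < 1:
            raise ConfigError(f"serum_bins must be >= 1, got {self.serum_bins}")
        if self.ligand_low >= self.ligand_high:
            raise ConfigError(
                f"ligand_low must be < ligand_high, got {self.ligand_low} >= {self.ligand_high}"
            )
        if not 0.0 <= self.mch_lo_frac < self.mch_hi_frac <= 1.0:
            raise ConfigError(
                f"need 0 <= mch_lo_frac < mch_hi_frac <= 1, got "
                f"{self.mch_lo_frac}, {self.mch_hi_frac}"
            )
        for ev in self.perturbations.events:
            # perturbation times must sit on the step grid
            k = ev.time_h / self.dt_hours
            if abs(k - round(k)) > 1e-9:
                raise ConfigError(
                    f"perturbation time {ev.time_h} h does not fall on the "
                    f"{self.dt_hours} h step grid"
                )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 24.0 / self.dt_hours))

    def with_(self, **kwargs: Any) -> "SimConfig":
        """Return a copy with fields replaced (validation re-runs)."""
        return replace(self, **kwargs)


def _config_to_dict(config: SimConfig) -> dict[str, Any]:
    d = asdict(config)
    d["perturbations"] = [
        {"time_h": ev.time_h, "kind": ev.kind, **dict(ev.params)}
        for ev in config.perturbations.events
    ]
    d["affinity"] = {
        "base_affinity_by_germline": dict(config.affinity.base_affinity_by_germline),
        "mutation_effects": dict(config.affinity.mutation_effects),
        "lethal_fraction": config.affinity.lethal_fraction,
        "key_site_probability": config.affinity.key_site_probability,
        "high_affinity_germline": config.affinity.high_affinity_germline,
    }
    return d


def _config_from_dict(d: dict[str, Any]) -> SimConfig:
    d = dict(d)
    pert = d.pop("perturbations", [])
    events = []
    for ev in pert:
        ev = dict(ev)
        t = ev.pop("time_h")
        kind = ev.pop("kind")
        events.append(PerturbationEvent(float(t), kind, tuple(sorted(ev.items()))))
    aff = d.pop("affinity", None)
    kwargs: dict[str, Any] = dict(d)
    kwargs["perturbations"] = PerturbationSchedule(tuple(events))
    if aff is not None:
        kwargs["affinity"] = AffinityModel(**aff)
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(kwargs) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    return SimConfig(**kwargs)


def load_config(path: str) -> SimConfig:
    """Load and validate a YAML config; omitted fields take defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return _config_from_dict(raw)


def dump_config(config: SimConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
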