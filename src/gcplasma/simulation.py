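"""Discrete-time stochastic agent-based GC -> plasma-cell simulation.

The model: light-zone (LZ) B cells capture antigen in proportion to
receptor affinity (Hill-saturating), present it to a T-follicular-helper
pool of fixed total capacity, and receive help in proportion to their
share of total capture.  Help sets Myc linearly; Myc sets the mean of a
Poisson division burst.  Entry into the plasma-cell precursor (prePC)
fate is affinity-INDEPENDENT (permissive selection), but a prePC stores
the Myc earned in its last LZ visit and, on maturing to a plasma cell
(PC), executes a division burst proportional to that stored Myc --
"inertial" division requiring no further T-cell help.  Dark-zone (DZ)
divisions hypermutate the receptor; PC divisions do not.

Pharmacological perturbations: anti-CD40L zeroes help, blocks LZ exits
and kills GC cells; TACI-Ig kills PCs; FTY720 blocks PC egress;
anti-IL21R halves the PC burst; DEC-OVA supplies receptor-independent
antigen so every LZ cell receives dose-proportional help; tamoxifen /
doxycycline drive the fate-map and division-dilution reporters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cells import Cell, BcrGenotype, affinity_of
from .config import (
    AffinityModel,
    HOTSPOT_MUTATIONS,
    HOTSPOT_POSITIONS,
    HIGH_AFFINITY_GERMLINE,
    LOW_AFFINITY_GERMLINES,
    LIGHT_GERMLINE,
    SimConfig,
)

_NT = "ACGT"
_JUNCTION_LEN = 21  # nt, in frame (7 codons)

# rng stream names, spawned deterministically from the root seed
_STREAMS = ("founding", "fate", "shm", "division", "pc", "death", "egress", "sampling")


@dataclass
class SimState:
    """Full simulation state: cell population, serum pool, clock, flags."""

    config: SimConfig
    clock_h: float
    cells: list[Cell]
    serum: np.ndarray
    serum_bin_centers: np.ndarray
    rngs: dict[str, np.random.Generator]
    #: egressed PCs keep secreting into the (systemic) serum but never
    #: re-enter node sampling; they are tracked as per-affinity-bin counts
    #: decayed at the PC death rate rather than as individual agents
    egressed_pcs: np.ndarray = None  # type: ignore[assignment]
    flags: dict[str, object] = field(default_factory=dict)
    event_log: list[tuple] = field(default_factory=list)
    next_cell_id: int = 0
    mutation_serial: int = 0
    founder_total: int = 0
    _applied_events: int = 0
    dec_expiry_h: float = -1.0
    _bin_cache: dict = field(default_factory=dict)

    # -- convenience ---------------------------------------------------
    def live_cells(self, compartments: Iterable[str] | None = None,
                   include_egressed: bool = False) -> list[Cell]:
        comps = set(compartments) if compartments is not None else None
        out = []
        for c in self.cells:
            if not c.alive:
                continue
            if c.egressed and not include_egressed:
                continue
            if comps is not None and c.compartment not in comps:
                continue
            out.append(c)
        return out

    def counts(self) -> dict[str, int]:
        out = {"LZ": 0, "DZ": 0, "prePC": 0, "PC": 0}
        for c in self.cells:
            if c.alive and not c.egressed:
                out[c.compartment] += 1
        return out

    @property
    def day(self) -> float:
        return self.clock_h / 24.0

    def copy(self) -> "SimState":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# elementary model operations
# ---------------------------------------------------------------------------

def capture_antigen(affinity: float, antigen_level: float, config: SimConfig) -> float:
    """Hill-saturating antigen capture: ``antigen * a^h / (a^h + K^h)``."""
    if affinity <= 0.0 or antigen_level <= 0.0:
        return 0.0
    ah = affinity ** config.hill
    return antigen_level * ah / (ah + config.capture_k ** config.hill)


def allocate_help(captures: Sequence[float], tfh_capacity: float) -> np.ndarray:
    """Split the Tfh help capacity among LZ cells pro rata by capture.

    Conserves the full capacity exactly whenever any capture is positive.
    """
    c = np.asarray(captures, dtype=float)
    total = c.sum()
    if total <= 0.0:
        return np.zeros_like(c)
    return tfh_capacity * c / total


def myc_from_help(help_: float, config: SimConfig) -> float:
    """Myc is linear in received help."""
    return config.beta * help_


def division_burst(
    myc: float,
    config: SimConfig,
    rng: np.random.Generator,
    alpha: float | None = None,
    modifier: float = 1.0,
) -> int:
    """Poisson division burst with mean ``alpha * myc * modifier``, capped at n_max."""
    a = config.alpha if alpha is None else alpha
    lam = a * myc * modifier
    if lam <= 0.0:
        return 0
    return int(min(config.n_max, rng.poisson(lam)))


def reentry_probability(help_: float, config: SimConfig) -> float:
    """DZ re-entry probability, saturating in help; zero help -> certain death."""
    if help_ <= 0.0:
        return 0.0
    if config.reentry_half_help == 0.0:
        return 1.0
    return help_ / (help_ + config.reentry_half_help)


def fate_draw(cell: Cell, help_: float, config: SimConfig, rng: np.random.Generator) -> str:
    """LZ fate: prePC export (affinity- and help-independent), DZ re-entry, or death."""
    if rng.random() < config.p_prepc:
        return "prePC"
    if rng.random() < reentry_probability(help_, config):
        return "DZ"
    return "death"


def mutate(
    genotype: BcrGenotype,
    rng: np.random.Generator,
    model: AffinityModel,
    shm_rate: float,
    serial: int,
) -> tuple[BcrGenotype | None, int]:
    """One somatic-hypermutation opportunity (per DZ division).

    With probability ``shm_rate`` one mutation is acquired: lethal
    (cell dies, returns ``None``), a heavy-chain hotspot (only on the
    high-affinity-capable germline, only if still absent), or a neutral
    substitution at a fresh position.  Returns the (possibly unchanged)
    genotype and the updated neutral-mutation serial counter.
    """
    if rng.random() >= shm_rate:
        return genotype, serial
    u = rng.random()
    if u < model.lethal_fraction:
        return None, serial
    if u < model.lethal_fraction + model.key_site_probability:
        if genotype.germline_v_heavy == model.high_affinity_germline:
            missing = sorted(set(HOTSPOT_MUTATIONS) - genotype.mutations_heavy)
            if missing:
                pick = missing[rng.integers(len(missing))]
                return genotype.with_heavy(pick), serial
        # fall through to a neutral mutation
    # neutral: random codon position outside the hotspot sites
    while True:
        pos = int(rng.integers(1, 121))
        if pos not in HOTSPOT_POSITIONS.values():
            break
    label = f"n{pos}u{serial}"
    if rng.random() < 2.0 / 3.0:  # heavy chain is the longer target
        return genotype.with_heavy(label), serial + 1
    return genotype.with_light(label), serial + 1


# ---------------------------------------------------------------------------
# state construction
# ---------------------------------------------------------------------------

def _serum_bins(config: SimConfig) -> np.ndarray:
    """Geometric affinity-bin centers spanning ``serum_decades`` around a0."""
    a0 = config.affinity.base_affinity_by_germline[config.affinity.high_affinity_germline]
    half = config.serum_decades / 2.0
    lo, hi = np.log10(a0) - half, np.log10(a0) + half
    edges = np.logspace(lo, hi, config.serum_bins + 1)
    return np.sqrt(edges[:-1] * edges[1:])


def serum_bin_index(affinity: float, config: SimConfig) -> int:
    a0 = config.affinity.base_affinity_by_germline[config.affinity.high_affinity_germline]
    half = config.serum_decades / 2.0
    lo, hi = np.log10(a0) - half, np.log10(a0) + half
    x = (np.log10(max(affinity, 1e-300)) - lo) / (hi - lo) * config.serum_bins
    return int(np.clip(np.floor(x), 0, config.serum_bins - 1))


def _random_junction(rng: np.random.Generator) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=_JUNCTION_LEN))


def init_simulation(config: SimConfig) -> SimState:
    """Seed ``founder_count`` unmutated LZ founder clones."""
    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(_STREAMS, ss.spawn(len(_STREAMS)))}
    state = SimState(
        config=config,
        clock_h=0.0,
        cells=[],
        serum=np.zeros(config.serum_bins),
        serum_bin_centers=_serum_bins(config),
        egressed_pcs=np.zeros(config.serum_bins),
        rngs=rngs,
    )
    frng = rngs["founding"]
    seen_junctions: set[str] = set()
    for i in range(config.founder_count):
        high = frng.random() < config.fraction_high_affinity_germline
        if high:
            vh = HIGH_AFFINITY_GERMLINE
        else:
            lows = [g for g in LOW_AFFINITY_GERMLINES
                    if g in config.affinity.base_affinity_by_germline]
            vh = lows[frng.integers(len(lows))] if lows else HIGH_AFFINITY_GERMLINE
        while True:  # junctions identify clones: force uniqueness
            jh = _random_junction(frng)
            if jh not in seen_junctions:
                seen_junctions.add(jh)
                break
        jl = _random_junction(frng)
        gt = BcrGenotype(vh, LIGHT_GERMLINE, jh, jl)
        cell = Cell(
            id=state.next_cell_id,
            founder_id=i,
            genotype=gt,
            compartment="LZ",
            affinity=affinity_of(gt, config.affinity),
        )
        state.cells.append(cell)
        state.event_log.append(("found", 0.0, cell.id, vh))
        state.next_cell_id += 1
    state.founder_total = config.founder_count
    return state


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def apply_label(state: SimState, kind: str) -> SimState:
    """Apply a reporter event in place and return the state.

    ``tamoxifen_s1pr2`` heritably labels current GC-resident cells
    (LZ/DZ/prePC); ``tamoxifen_blimp1`` heritably labels current PCs;
    ``doxycycline`` stops label synthesis so each later division halves
    the division-dilution label.
    """
    if kind == "tamoxifen_s1pr2":
        for c in state.cells:
            if c.alive and c.compartment in ("LZ", "DZ", "prePC"):
                c.label_s1pr2 = True
    elif kind == "tamoxifen_blimp1":
        for c in state.cells:
            if c.alive and c.compartment == "PC":
                c.label_blimp1 = True
    elif kind == "doxycycline":
        state.flags["doxycycline"] = True
    else:
        raise ValueError(f"unknown label kind {kind!r}")
    state.event_log.append(("label", state.clock_h, kind))
    return state


# ---------------------------------------------------------------------------
# the scheduler
# ---------------------------------------------------------------------------

def _activate_perturbations(state: SimState) -> None:
    events = state.config.perturbations.events
    while state._applied_events < len(events):
        ev = events[state._applied_events]
        if ev.time_h > state.clock_h + 1e-9:
            break
        if ev.kind in ("tamoxifen_s1pr2", "tamoxifen_blimp1", "doxycycline"):
            apply_label(state, ev.kind)
        elif ev.kind == "DEC_OVA":
            state.flags["DEC_OVA"] = float(ev.param_dict["dose"])
            state.dec_expiry_h = ev.time_h + state.config.dec_duration_h
            state.event_log.append(("perturb", state.clock_h, ev.kind, float(ev.param_dict["dose"])))
        else:
            state.flags[ev.kind] = True
            state.event_log.append(("perturb", state.clock_h, ev.kind))
        state._applied_events += 1
    if "DEC_OVA" in state.flags and state.clock_h >= state.dec_expiry_h - 1e-9:
        del state.flags["DEC_OVA"]


def _divide(state: SimState, parent: Cell, compartment: str) -> Cell:
    """Execute one division: parent persists as one daughter, a new cell is
    the other.  Returns the new cell (genotype still the parent's)."""
    dox = bool(state.flags.get("doxycycline"))
    parent.pending_divisions -= 1
    parent.division_count += 1
    if compartment == "PC":
        parent.pc_division_count += 1
    if dox:
        parent.label_divisions += 1
    child = Cell(
        id=state.next_cell_id,
        founder_id=parent.founder_id,
        genotype=parent.genotype,
        compartment=compartment,
        affinity=parent.affinity,
        parent_id=parent.id,
        myc=parent.myc,
        pending_divisions=parent.pending_divisions,
        division_count=parent.division_count,
        label_s1pr2=parent.label_s1pr2,
        label_blimp1=parent.label_blimp1,
        label_divisions=parent.label_divisions,
        pc_division_count=parent.pc_division_count,
        egressed=parent.egressed,
    )
    state.next_cell_id += 1
    state.cells.append(child)
    state.event_log.append(("div", state.clock_h, parent.id, child.id, compartment))
    return child


def step(state: SimState) -> SimState:
    """Advance the state by one time step (in place; returns the state).

    Fixed phase order: perturbation activation -> LZ selection -> DZ
    division/mutation -> prePC maturation -> PC inertial division ->
    deaths -> antibody secretion -> egress.
    """
    cfg = state.config
    _activate_perturbations(state)
    cd40l = bool(state.flags.get("anti_CD40L"))
    fate_rng = state.rngs["fate"]
    div_rng = state.rngs["division"]
    shm_rng = state.rngs["shm"]
    pc_rng = state.rngs["pc"]
    death_rng = state.rngs["death"]
    egress_rng = state.rngs["egress"]

    # --- LZ selection (suppressed by anti-CD40L: no help, no LZ exits) ---
    if not cd40l:
        lz = [c for c in state.cells if c.alive and c.compartment == "LZ"]
        if lz:
            caps = [capture_antigen(c.affinity, cfg.antigen_level, cfg) for c in lz]
            helps = allocate_help(caps, cfg.tfh_capacity)
            if cfg.help_cap > 0:
                # per-cell absorption ceiling (synapse saturation);
                # unused capacity is wasted, not redistributed
                helps = np.minimum(helps, cfg.help_cap)
            dec_dose = state.flags.get("DEC_OVA")
            if dec_dose is not None:
                # targeted antigen reaches every GC B cell independent of its
                # receptor, adding dose-proportional presentation on top of
                # BCR-mediated capture
                helps = helps + cfg.dec_help_coef * float(dec_dose)
            for cell, h in zip(lz, helps):
                m = myc_from_help(float(h), cfg)
                fate = fate_draw(cell, float(h), cfg, fate_rng)
                if fate == "prePC":
                    cell.compartment = "prePC"
                    cell.myc = m  # the stored "historic" selection signal
                    cell.prepc_age = 0
                    state.event_log.append(("export", state.clock_h, cell.id))
                elif fate == "DZ":
                    cell.compartment = "DZ"
                    cell.myc = m
                    cell.pending_divisions = division_burst(m, cfg, div_rng)
                else:
                    cell.alive = False
                    state.event_log.append(("death", state.clock_h, cell.id, "LZ"))

    # --- DZ divisions with somatic hypermutation ---
    dz = [c for c in state.cells if c.alive and c.compartment == "DZ"]
    for cell in dz:
        if cd40l:
            # CD40L blockade halts the GC proliferative program
            cell.pending_divisions = 0
            continue
        if cell.pending_divisions > 0:
            child = _divide(state, cell, "DZ")
            new_gt, state.mutation_serial = mutate(
                child.genotype, shm_rng, cfg.affinity, cfg.shm_rate, state.mutation_serial
            )
            if new_gt is None:
                child.alive = False
                state.event_log.append(("death", state.clock_h, child.id, "lethal"))
            elif new_gt is not child.genotype:
                child.genotype = new_gt
                child.affinity = affinity_of(new_gt, cfg.affinity)
                state.event_log.append(("mut", state.clock_h, child.id))
        else:
            cell.compartment = "LZ"
            cell.myc = 0.0

    # --- prePC -> PC maturation, granting the inertial burst ---
    il21 = cfg.il21_burst * (cfg.anti_il21r_factor if state.flags.get("anti_IL21R") else 1.0)
    for cell in state.cells:
        if cell.alive and cell.compartment == "prePC":
            if cell.prepc_age >= cfg.prepc_maturation_steps:
                cell.compartment = "PC"
                cell.pending_divisions = division_burst(
                    cell.myc, cfg, pc_rng, alpha=cfg.alpha_pc, modifier=il21
                )
                state.event_log.append(("mature", state.clock_h, cell.id))
            else:
                cell.prepc_age += 1

    # --- PC inertial divisions (no mutation; CD40L-independent) ---
    pcs = [c for c in state.cells if c.alive and c.compartment == "PC"]
    for _ in range(cfg.pc_divisions_per_step):
        pending = [c for c in pcs if c.pending_divisions > 0]
        if not pending:
            break
        draws = pc_rng.random(len(pending))
        new_pcs = [
            _divide(state, cell, "PC")
            for cell, u in zip(pending, draws)
            if u < cfg.pc_division_prob
        ]
        pcs = pcs + new_pcs

    # --- deaths ---
    taci = bool(state.flags.get("TACI_Ig"))
    gc_p = min(cfg.cd40l_gc_death if cd40l else cfg.gc_death, 1.0)
    pc_p = min(cfg.pc_death + (cfg.taci_pc_death if taci else 0.0), 1.0)
    live = [c for c in state.cells if c.alive]
    if gc_p > 0.0 or pc_p > 0.0:
        draws = death_rng.random(len(live))
        for cell, u in zip(live, draws):
            p = pc_p if cell.compartment == "PC" else gc_p
            if u < p:
                cell.alive = False
                state.event_log.append(("death", state.clock_h, cell.id, cell.compartment))
    if pc_p > 0.0:
        state.egressed_pcs *= 1.0 - pc_p

    # --- secretion (all live PCs, egressed included: serum is systemic) ---
    cache = state._bin_cache
    for cell in state.cells:
        if cell.alive and cell.compartment == "PC":
            b = cache.get(cell.affinity)
            if b is None:
                b = cache[cell.affinity] = serum_bin_index(cell.affinity, cfg)
            state.serum[b] += cfg.secretion_rate
    state.serum += cfg.secretion_rate * state.egressed_pcs

    # --- egress (actively bursting plasmablasts stay in the node; a cell
    # finishing its burst either settles as a resident medullary PC or
    # becomes egress-prone) ---
    if not state.flags.get("FTY720"):
        for cell in state.cells:
            if (cell.alive and cell.compartment == "PC" and not cell.egressed
                    and cell.pending_divisions == 0):
                if not cell.residency_checked:
                    cell.residency_checked = True
                    # locally expanded plasmablasts can settle in the
                    # medullary cords; never-divided exports just pass through
                    if (cell.pc_division_count > 0
                            and egress_rng.random() < cfg.pc_resident_prob):
                        cell.resident = True
                if not cell.resident and egress_rng.random() < cfg.egress_prob:
                    cell.egressed = True
                    cell.alive = False  # leaves the node: aggregated below
                    b = cache.get(cell.affinity)
                    if b is None:
                        b = cache[cell.affinity] = serum_bin_index(cell.affinity, cfg)
                    state.egressed_pcs[b] += 1.0
                    state.event_log.append(("egress", state.clock_h, cell.id))

    state.cells = [c for c in state.cells if c.alive]
    state.clock_h += cfg.dt_hours
    return state


def run_until(state: SimState, day: float) -> SimState:
    while state.clock_h < day * 24.0 - 1e-9:
        step(state)
    return state


def run(config: SimConfig) -> SimState:
    state = init_simulation(config)
    return run_until(state, config.duration_days)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def serum_avidity_ratio(
    serum: np.ndarray,
    bin_centers: np.ndarray,
    ligand_low: float,
    ligand_high: float,
) -> float:
    """Ratio of serum binding to sparse vs dense hapten carrier.

    Per-bin fractional occupancy theta(a, L) = a*L / (1 + a*L) weighted by
    accumulated antibody; the ratio rises as antibody mass shifts to
    higher-affinity bins (NP7/NP28 ELISA analog).
    """
    if ligand_low >= ligand_high:
        raise ValueError(f"ligand_low must be < ligand_high, got {ligand_low} >= {ligand_high}")
    w = np.asarray(serum, dtype=float)
    if w.sum() <= 0.0:
        raise ValueError("serum is empty: avidity ratio undefined")
    a = np.asarray(bin_centers, dtype=float)
    lo = float(np.sum(w * a * ligand_low / (1.0 + a * ligand_low)))
    hi = float(np.sum(w * a * ligand_high / (1.0 + a * ligand_high)))
    return lo / hi


def state_avidity_ratio(state: SimState) -> float:
    return serum_avidity_ratio(
        state.serum, state.serum_bin_centers, state.config.ligand_low, state.config.ligand_high
    )


def sample_cells(
    state: SimState,
    compartments: Iterable[str] | None = None,
    label: str | None = None,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    mouse_id: str = "m0",
) -> pd.DataFrame:
    """Flow-sort analog: uniform subsample of matching live, non-egressed
    cells exported as a cell table (see :mod:`gcplasma.tables`).

    ``label`` filters on a fate-map reporter: ``"s1pr2"`` or ``"blimp1"``.
    """
    from .tables import cells_to_table

    pool = state.live_cells(compartments)
    if label == "s1pr2":
        pool = [c for c in pool if c.label_s1pr2]
    elif label == "blimp1":
        pool = [c for c in pool if c.label_blimp1]
    elif label is not None:
        raise ValueError(f"unknown label filter {label!r}")
    if n is not None and n < len(pool):
        rng = state.rngs["sampling"] if rng is None else rng
        idx = rng.choice(len(pool), size=n, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    return cells_to_table(pool, state.config, mouse_id=mouse_id)
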