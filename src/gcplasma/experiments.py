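"""Scripted in-silico experimental designs.

Four classic lymph-node experiments are wired end to end (simulator ->
repertoire -> stats) across replicate seeds ("mice"): a fate-map
repertoire comparison, division-dilution tracking, GC ablation with
serology, and graded targeted-antigen delivery. Each runner returns
per-seed and pooled summary tables and machine-evaluates the design's
qualitative assertions. Day-to-step mappings are documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import (
    HIGH_AFFINITY_GERMLINE,
    PerturbationSchedule,
    SimConfig,
)
from .repertoire import summarize
from .simulation import (
    init_simulation,
    run,
    run_until,
    sample_cells,
    state_avidity_ratio,
)
from .stats import chao1, clone_abundances, clone_size_summary, gate_label


@dataclass
class ExperimentReport:
    experiment: str
    per_seed: pd.DataFrame
    pooled: pd.DataFrame
    assertions: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.assertions.values())

    def to_text(self) -> str:
        lines = [f"experiment: {self.experiment}", "", "pooled summary:",
                 self.pooled.to_string(), "", "assertions:"]
        for name, ok in self.assertions.items():
            lines.append(f"  [{'PASS' if ok else 'FAIL'}] {name}")
        return "\n".join(lines)


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic distinct per-mouse seeds derived from one root seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]  # keep below 2**31


def _pool(per_seed: pd.DataFrame, drop: tuple[str, ...] = ("seed",)) -> pd.DataFrame:
    num = per_seed.drop(columns=[c for c in drop if c in per_seed.columns])
    num = num.select_dtypes("number")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


# ---------------------------------------------------------------------------
# fig1: fate-map labeling day 5, paired sequencing of labeled
# GC B cells and PCs on day 14
# ---------------------------------------------------------------------------

def run_fig1_analog(
    config: SimConfig | None = None,
    n_seeds: int = 10,
    base_seed: int = 0,
    sample_n: int | None = None,
) -> ExperimentReport:
    """Clonal-node analysis of contemporaneous labeled GC B cells and PCs.

    Asserts the expected qualitative pattern: PCs are enriched for
    affinity-enhancing hotspot mutations over contemporaneous GC B cells,
    PC-only nodes are the rarest class, and mixed GC/PC nodes are the
    largest and hold most PCs.
    """
    base = config if config is not None else SimConfig()
    sched = PerturbationSchedule.of((120.0, "tamoxifen_s1pr2"))
    tables = []
    for i, seed in enumerate(replicate_seeds(base_seed, n_seeds)):
        cfg = base.with_(seed=seed, duration_days=14.0, perturbations=sched)
        state = run(cfg)
        mouse = f"m{i}"
        gc = sample_cells(state, ("LZ", "DZ"), label="s1pr2", n=sample_n, mouse_id=mouse)
        pc = sample_cells(state, ("PC",), label="s1pr2", n=sample_n, mouse_id=mouse)
        tables.append(pd.concat([gc, pc], ignore_index=True))
    table = pd.concat(tables, ignore_index=True)
    summary = summarize(table)
    per_seed = summary.per_mouse.copy()
    per_seed.insert(0, "seed", replicate_seeds(base_seed, n_seeds))
    pooled = summary.pooled
    mean = pooled["mean"]
    n_enriched = int(
        (per_seed["pc_hotspot_fraction"] > per_seed["gc_hotspot_fraction"]).sum()
    )
    assertions = {
        "pc_hotspot_fraction_exceeds_gc_pooled": bool(
            mean["pc_hotspot_fraction"] > mean["gc_hotspot_fraction"]
        ),
        "pc_only_nodes_least_abundant": bool(
            mean["nodes_pc_only"] < mean["nodes_gc_only"]
            and mean["nodes_pc_only"] < mean["nodes_mixed"]
        ),
        "mixed_nodes_largest": bool(
            mean["mean_size_mixed"] > mean["mean_size_gc_only"]
            and mean["mean_size_mixed"] > mean["mean_size_pc_only"]
        ),
        "most_pcs_in_mixed_nodes": bool(mean["frac_pcs_in_mixed_nodes"] > 0.5),
    }
    report = ExperimentReport("fig1", per_seed, pooled, assertions)
    report.n_seeds_pc_enriched = n_enriched  # type: ignore[attr-defined]
    return report


# ---------------------------------------------------------------------------
# fig2: doxycycline day 10, division-gated PCs on day 12
# ---------------------------------------------------------------------------

def run_fig2_analog(
    config: SimConfig | None = None,
    n_seeds: int = 10,
    base_seed: int = 0,
) -> ExperimentReport:
    """Division-dilution gating of PCs two days after label switch-off.

    The well-divided (label-lo) gate should carry a higher fraction of
    high-affinity-germline receptors, a larger expanded-clone fraction,
    and lower Chao1 richness than the undivided (label-hi) gate.
    """
    base = config if config is not None else SimConfig()
    sched = PerturbationSchedule.of((240.0, "doxycycline"))
    rows = []
    for i, seed in enumerate(replicate_seeds(base_seed, n_seeds)):
        cfg = base.with_(seed=seed, duration_days=12.0, perturbations=sched)
        state = run(cfg)
        pcs = sample_cells(state, ("PC",), mouse_id=f"m{i}")
        gated = gate_label(
            pcs, cfg.label_l0 * cfg.mch_lo_frac, cfg.label_l0 * cfg.mch_hi_frac
        )
        row: dict = {"seed": seed}
        subs = {g_: gated[gated["gate"] == g_] for g_ in ("lo", "hi")}
        # sequence both gates to a common depth, as paired single-cell
        # libraries are: richness and clonality are depth-sensitive
        depth = min(min(len(s) for s in subs.values()), 300)
        srng = np.random.default_rng(seed)
        for gate, sub in subs.items():
            row[f"n_{gate}"] = len(sub)
            if depth < 10:
                row[f"high_germline_frac_{gate}"] = float("nan")
                row[f"expanded_frac_{gate}"] = float("nan")
                row[f"chao1_{gate}"] = float("nan")
                continue
            take = sub.iloc[sorted(srng.choice(len(sub), size=depth, replace=False))]
            row[f"high_germline_frac_{gate}"] = float(
                (take["v_call"] == HIGH_AFFINITY_GERMLINE).mean()
            )
            row[f"expanded_frac_{gate}"] = clone_size_summary(take).expanded_fraction
            row[f"chao1_{gate}"] = chao1(clone_abundances(take))
        rows.append(row)
    per_seed = pd.DataFrame(rows)

    def _majority(cmp: pd.Series) -> bool:
        return bool(cmp.sum() > len(per_seed) / 2)

    assertions = {
        "lo_gate_higher_high_affinity_germline_fraction": _majority(
            per_seed["high_germline_frac_lo"] > per_seed["high_germline_frac_hi"]
        ),
        "lo_gate_higher_expanded_clone_fraction": _majority(
            per_seed["expanded_frac_lo"] > per_seed["expanded_frac_hi"]
        ),
        "lo_gate_lower_chao1": _majority(per_seed["chao1_lo"] < per_seed["chao1_hi"]),
    }
    return ExperimentReport("fig2", per_seed, _pool(per_seed), assertions)


# ---------------------------------------------------------------------------
# fig4: GC ablation day 10 under egress blockade; repertoire at
# days 10/16, serum avidity at days 12/32; PC depletion control
# ---------------------------------------------------------------------------

_FIG4_ARMS = ("control", "anti_CD40L", "anti_CD40L+TACI_Ig")


def _fig4_schedule(arm: str) -> PerturbationSchedule:
    events = [(192.0, "tamoxifen_s1pr2"), (192.0, "FTY720")]
    if arm in ("anti_CD40L", "anti_CD40L+TACI_Ig"):
        events.append((240.0, "anti_CD40L"))
    if arm == "anti_CD40L+TACI_Ig":
        events.append((240.0, "TACI_Ig"))
    return PerturbationSchedule.of(*events)


def run_fig4_analog(
    config: SimConfig | None = None,
    n_seeds: int = 5,
    base_seed: int = 0,
) -> ExperimentReport:
    """GC-independent affinity maturation of the labeled PC compartment.

    Fate-map + egress blockade day 8, GC ablation (anti-CD40L) day 10,
    optional PC depletion (TACI-Ig) day 10.  The high-affinity-germline
    fraction among labeled PCs should rise from day 10 to day 16 with or
    without an intact GC; the serum avidity ratio should rise from day 12
    to day 32 in both but not when PCs are depleted; and ablated-arm PCs
    should carry fewer mutations than control (earlier GC exits).
    """
    # a moderately sized lymph node keeps the 32-day, three-arm design fast
    base = config if config is not None else SimConfig().with_(
        founder_count=150, tfh_capacity=200.0
    )
    rows = []
    for seed in replicate_seeds(base_seed, n_seeds):
        for arm in _FIG4_ARMS:
            cfg = base.with_(
                seed=seed, duration_days=32.0, perturbations=_fig4_schedule(arm)
            )
            state = init_simulation(cfg)
            run_until(state, 10.0)
            pc10 = sample_cells(state, ("PC",), label="s1pr2")
            f10 = (
                float((pc10["v_call"] == HIGH_AFFINITY_GERMLINE).mean())
                if len(pc10)
                else float("nan")
            )
            run_until(state, 12.0)
            r12 = state_avidity_ratio(state)
            run_until(state, 16.0)
            pc16 = sample_cells(state, ("PC",), label="s1pr2")
            if len(pc16):
                f16 = float((pc16["v_call"] == HIGH_AFFINITY_GERMLINE).mean())
                load16 = float(
                    summarize(pc16).per_mouse["mean_mutation_load_pc"].iloc[0]
                )
            else:
                f16 = load16 = float("nan")
            run_until(state, 32.0)
            r32 = state_avidity_ratio(state)
            rows.append(
                {
                    "seed": seed,
                    "arm": arm,
                    "pc_high_germline_frac_d10": f10,
                    "pc_high_germline_frac_d16": f16,
                    "serum_ratio_d12": r12,
                    "serum_ratio_d32": r32,
                    "serum_ratio_rise": r32 - r12,
                    "pc_mutation_load_d16": load16,
                    "n_pc_d10": len(pc10),
                    "n_pc_d16": len(pc16),
                }
            )
    per_seed = pd.DataFrame(rows)
    pooled = per_seed.groupby("arm").agg(["mean", "std"])
    arm_mean = per_seed.groupby("arm").mean(numeric_only=True)
    rise = arm_mean["serum_ratio_rise"]
    assertions = {
        "high_affinity_fraction_rises_control": bool(
            arm_mean.loc["control", "pc_high_germline_frac_d16"]
            > arm_mean.loc["control", "pc_high_germline_frac_d10"]
        ),
        "high_affinity_fraction_rises_anti_CD40L": bool(
            arm_mean.loc["anti_CD40L", "pc_high_germline_frac_d16"]
            > arm_mean.loc["anti_CD40L", "pc_high_germline_frac_d10"]
        ),
        "serum_ratio_rises_control": bool(rise["control"] > 0),
        "serum_ratio_rises_anti_CD40L": bool(rise["anti_CD40L"] > 0),
        "taci_abolishes_serum_rise": bool(
            rise["anti_CD40L+TACI_Ig"] < 0.2 * rise["anti_CD40L"]
        ),
        "anti_CD40L_lowers_mutation_load": bool(
            arm_mean.loc["anti_CD40L", "pc_mutation_load_d16"]
            < arm_mean.loc["control", "pc_mutation_load_d16"]
        ),
    }
    return ExperimentReport("fig4", per_seed, pooled, assertions)


# ---------------------------------------------------------------------------
# fig5: graded receptor-independent antigen delivery into an
# ongoing GC, with or without anti-CD40L 12 h later
# ---------------------------------------------------------------------------

def run_fig5_analog(
    config: SimConfig | None = None,
    doses: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0),
    n_seeds: int = 5,
    base_seed: int = 0,
) -> ExperimentReport:
    """Dose-proportionality of GC expansion, prePC Myc and PC division.

    Phase A: targeted antigen at day 10, readout at +24 h (GC size, prePC
    number and mean stored Myc, each monotone in dose).  Phase B: the
    same delivery followed by anti-CD40L at +12 h -- GC division events
    must cease within 1 day while PC division events continue for at
    least 2 days, with cumulative PC divisions monotone in dose.
    """
    base = config if config is not None else SimConfig()
    t_dec, t_cd40l = 240.0, 252.0
    rows = []
    for seed in replicate_seeds(base_seed, n_seeds):
        for dose in doses:
            # phase A: readout 24 h after delivery
            sched_a = (
                PerturbationSchedule.of((t_dec, "DEC_OVA", {"dose": dose}))
                if dose > 0
                else PerturbationSchedule()
            )
            cfg = base.with_(seed=seed, duration_days=11.0, perturbations=sched_a)
            state = run(cfg)
            counts = state.counts()
            prepcs = state.live_cells(("prePC",))
            row = {
                "seed": seed,
                "dose": dose,
                "gc_size_24h": counts["LZ"] + counts["DZ"],
                "prepc_n_24h": counts["prePC"],
                "prepc_myc_24h": (
                    float(np.mean([c.myc for c in prepcs])) if prepcs else float("nan")
                ),
            }
            # phase B: anti-CD40L 12 h after delivery, run 3 more days
            events = [(t_cd40l, "anti_CD40L")]
            if dose > 0:
                events.insert(0, (t_dec, "DEC_OVA", {"dose": dose}))
            cfg_b = base.with_(
                seed=seed, duration_days=14.0, perturbations=PerturbationSchedule.of(*events)
            )
            state_b = run(cfg_b)
            gc_div_after = [
                ev[1] for ev in state_b.event_log
                if ev[0] == "div" and ev[4] == "DZ" and ev[1] >= t_cd40l
            ]
            pc_div_after = [
                ev[1] for ev in state_b.event_log
                if ev[0] == "div" and ev[4] == "PC" and ev[1] >= t_cd40l
            ]
            row["gc_divisions_after_cd40l_1d"] = sum(
                1 for t in gc_div_after if t > t_cd40l + 24.0
            )
            row["pc_divisions_at_2d"] = sum(1 for t in pc_div_after if t >= t_cd40l + 48.0)
            row["pc_divisions_total"] = len(pc_div_after)
            rows.append(row)
    per_seed = pd.DataFrame(rows)
    dose_means = per_seed.groupby("dose").mean(numeric_only=True).drop(columns=["seed"])

    def _monotone(col: str) -> bool:
        rho = spearmanr(dose_means.index.to_numpy(), dose_means[col].to_numpy()).statistic
        return bool(rho >= 0.999)

    assertions = {
        "gc_size_monotone_in_dose": _monotone("gc_size_24h"),
        "prepc_myc_monotone_in_dose": _monotone("prepc_myc_24h"),
        "pc_divisions_monotone_in_dose": _monotone("pc_divisions_total"),
        "gc_divisions_cease_within_1d": bool(
            per_seed["gc_divisions_after_cd40l_1d"].sum() == 0
        ),
        "pc_divisions_continue_2d": bool(
            (per_seed.loc[per_seed["dose"] > 0, "pc_divisions_at_2d"] > 0).all()
        ),
    }
    return ExperimentReport("fig5", per_seed, dose_means, assertions)
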