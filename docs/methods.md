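# Methods

## The model

`gcplasma` simulates one immunized lymph node as a discrete-time (6 h
step), stochastic agent-based system with four B-cell compartments —
light zone (LZ), dark zone (DZ), plasma-cell precursor (prePC) and
plasma cell (PC) — plus a systemic serum antibody pool. The question the
model is built around: selection into the PC fate is *permissive* with
respect to antibody affinity, yet the PC compartment affinity-matures.
The mechanism implemented is division-based: each exported precursor
carries the Myc it earned from T-follicular-helper (Tfh) help in its
last LZ visit, and executes a Myc-proportional burst of "inertial"
divisions after export, with no further T-cell input.

Per step, in fixed order:

1. **Perturbation activation.** Scheduled events switch reporter labels
   or pharmacological flags (see below).
2. **LZ selection.** Each LZ cell captures antigen with a saturating law
   `c = A · a/(a + K)` (affinity `a`, antigen level `A`, half-saturation
   `K`). A fixed Tfh help capacity `C` is split pro rata by capture
   (`h_i = C·c_i/Σc`), then clipped at a per-cell absorption ceiling
   (synapse saturation). Myc is linear in help (`m = β·h`). Each cell
   then draws a fate: prePC export with probability `p_PC`,
   **independent of affinity and help** (the permissiveness commitment,
   hard-coded); otherwise DZ re-entry with probability `h/(h + h₁∕₂)`,
   or death. DZ entrants receive a Poisson(α·m) division burst (capped);
   prePCs store `m` unmodified.
3. **DZ division.** One division per step while the burst lasts; each
   division appends one daughter. The daughter mutates with probability
   μ: lethal (cell dies), a heavy-chain hotspot (W33L/K59R/Y99G analogs,
   only on the high-affinity-capable germline), or neutral at a fresh
   codon. Keeping the parent's genotype fixed makes recorded parent links
   exact ancestral genotypes. Exhausted cells return to the LZ.
4. **prePC maturation.** After one step a prePC becomes a PC and is
   granted Poisson(α_PC · m · g_IL21) pending divisions — the inertial
   burst. α_PC ≫ α: plasmablast expansion is steeper in Myc than the DZ
   program.
5. **PC division.** Up to `pc_divisions_per_step` pending divisions
   execute per step (each with probability 0.8), **without mutation**.
6. **Deaths.** Per-compartment per-step probabilities;
   affinity-independent throughout (the shipped default encodes the
   finding that differential PC death does not drive enrichment).
7. **Secretion.** Every live PC adds antibody to a 32-bin logarithmic
   affinity histogram (6 decades around the analog germline baseline).
8. **Egress.** Actively bursting plasmablasts are retained in the node;
   a cell that completes its burst either settles as a resident
   medullary PC (probability 0.015, only if it actually divided) or
   becomes egress-prone (0.65/step). Egressed PCs keep secreting into
   the systemic serum but leave node sampling; they are tracked as
   per-bin counts with expected-value decay rather than as agents.

Perturbations: `tamoxifen_s1pr2` heritably labels current GC cells,
`tamoxifen_blimp1` current PCs; `doxycycline` freezes division-label
synthesis so the label halves per division (`L = L0·2^-k`, exact);
`anti_CD40L` zeroes help, blocks LZ exits, halts the GC proliferative
program and imposes a GC death rate that empties the GC within two
simulated days, while PC bursts run on; `anti_IL21R` halves the PC burst
mean; `TACI_Ig` kills PCs (including egressed ones); `FTY720` blocks
egress; `DEC_OVA(dose)` adds receptor-independent, dose-proportional
help to every LZ cell on top of BCR-mediated capture, for 24 h.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| `dt_hours` | 6 | two steps per LZ/DZ half-cycle |
| `founder_count` | 400 | founder clones seeding the GC |
| `fraction_high_affinity_germline` | 0.3 | founders using the IGHV1-72 analog |
| `tfh_capacity` (C) | 500 | help units dispensed per step |
| `capture_k` (K), `hill` | 4, 1 | capture half-saturation, Hill exponent |
| `help_cap` | 0.8 | max help absorbed per LZ visit |
| `beta` | 1 | help → Myc slope |
| `alpha` / `alpha_pc` | 0.5 / 10 | Myc → burst-mean slope (DZ / PC) |
| `il21_burst` | 1.5 | IL-21 multiplier on the PC burst mean |
| `n_max` | 8 | burst cap (a burst of n yields 2^n cells) |
| `p_prepc` | 0.05 | prePC export per LZ visit, affinity-independent |
| `shm_rate` (μ) | 0.3 | mutation probability per daughter per DZ division |
| `lethal_fraction` / `key_site_probability` | 0.3 / 0.25 | mutation-class split |
| germline baselines | 10 / 5 / 2.5 / 1 | a0 of IGHV1-72 and the graded non-analog classes |
| hotspot factors | ×10, ×2, ×2 | W33L, K59R, Y99G |
| `pc_death` | 0.05/step | ~0.2/day, affinity-independent |
| `egress_prob` | 0.65/step | idle PCs only; 0 under FTY720 |
| `ligand_low` / `ligand_high` | 0.01 / 0.04 | sparse/dense hapten carrier for the avidity ratio |

## Why these defaults

The proportionality statements the model implements are verbal in
origin, so the functional forms are the simplest that satisfy them
(saturating capture, linear Myc, Poisson bursts). The remaining freedom
was calibrated *once* against the day-12/day-14 repertoire regime the
study system exhibits: hotspot mutations essentially absent from PCs at
day 12, roughly half of GC B cells hotspot-positive at day 14 with large
mouse-to-mouse spread, and PCs consistently ahead of GC B cells. Three
features of the calibration deserve comment.

- **Gentle capture saturation and a help ceiling.** With steep capture
  (Hill 2) and an unbounded share, a hotspot clone's ~2× capture
  advantage compounds through DZ re-entry and bursts into fixation
  within a week — no mid-sweep repertoire would exist at day 14, and the
  no-inertial-division control could never equal the GC (the export
  stream would always lag a racing sweep). Hill 1, K = 4 and the
  per-visit absorption ceiling keep the within-GC sweep slow
  (~1.3×/day in odds) while leaving a real Myc difference for the PC
  burst to amplify.
- **A steep PC slope (α_PC = 10) with a moderate cap.** The inertial
  burst is the one-shot amplifier that converts a modest stored-Myc
  difference into a several-fold descendant difference; burst means must
  stay below the cap (λ ≈ 2–7) or truncation erases the contrast.
- **A high hotspot share of mutations (0.25).** Many parallel hotspot
  lineages (a soft sweep) make the day-14 hotspot fraction reproducible
  across replicate seeds; with rare hotspot events the establishment
  time, and hence the entire figure-level phenotype, is a lottery.

`alpha_pc = 0` is the null model used throughout: permissive export with
no inertial division, in which the PC pool is expected to mirror the
contemporaneous GC.

## What the generator emulates — and does not

One simulation is one "mouse"; replicates are i.i.d. seeds, and
figure-style analyses report per-mouse statistics (mean ± SD), matching
per-animal summaries. The cell table the simulator exports is
AIRR-flavored (paired heavy/light V calls, junctions, mutation lists,
compartment and reporter metadata), so the analysis pipeline is
identical for simulated and mapped real data. Not emulated: nucleotide-
level evolution (mutations are abstract codon-position tokens), V(D)J
assignment ambiguity, sequencing error and dropout, isotypes,
bone-marrow PC biology beyond egress, spatial structure, and
biological mouse-to-mouse variance beyond seed noise. Passing tests
therefore demonstrate that the *mechanism as modeled* produces the
claimed repertoire patterns under idealized measurement — not that real
data would yield the same effect sizes.

## Experiment analogs and day mappings

- **Fate-map comparison (day 14):** GC label at day 5; all labeled GC B
  and PCs are analyzed at day 14 (clones → identical-sequence nodes →
  GC-only/PC-only/mixed classes, hotspot scoring, lineage trees).
- **Division tracking (days 10→12):** label synthesis off at day 10;
  PCs gated at day 12 into well-divided (≥3 divisions, label ≤ L0/8)
  vs undivided (≤1 division, label ≥ L0/2); both gates are subsampled
  to a common depth (≤300) before richness/clonality statistics because
  Chao1 and expanded-clone fractions are depth-sensitive.
- **GC ablation (days 8–32):** GC label + egress block at day 8; arms
  {control, GC ablation, GC ablation + PC depletion} at day 10;
  repertoire at days 10/16, serum avidity ratio at days 12/32 ("several
  weeks" mapped to day 32). This analog runs a moderately sized node
  (150 founders, capacity 200) — a problem-size choice; readouts are
  fractions and ratios.
- **Graded antigen delivery (day 10):** doses (0, 2, 4, 8) of targeted
  antigen; GC size and prePC number/Myc at +24 h; in the second phase
  anti-CD40L at +12 h, division events tracked by compartment for 3
  days.

## Numerical choices and degenerate inputs

Random streams are spawned per purpose (founding, fate, mutation,
division, PC, death, egress, sampling) from one root seed; identical
config + seed gives bit-identical event logs. The division label is
stored as a division count, so `L·2^k = L0` holds exactly in floating
point. Help allocation conserves the dispensed capacity to ≤1e-9
relative error; an all-zero capture vector allocates nothing. Affinity
zero captures nothing; an empty serum raises rather than returning a
ratio. Lineage-tree linking is greedy maximum-subset with deterministic
tie-breaks (larger parent, then lexicographic node id); a virtual
germline root carries the empty mutation signature, and an unmutated
node attaches to it with edge length 0. Node statistics treat prePCs as
GC-phenotype cells (configurable). Empty compartments yield missing
values (NaN), never zeros.

## Known limitations

- The within-GC sweep still progresses at measurement time, so the null
  model shows a small negative PC-minus-GC gap (the export stream
  averages a slightly earlier GC); it is well within replicate noise at
  the shipped scale but is a structural property of any
  still-evolving GC.
- Hotspot effect sizes and slopes are coarse-grained aggregates; only
  their ordering and rough magnitudes are meaningful.
- The serum model ignores antibody decay within the ≤32-day horizon
  (except that PC depletion stops secretion), and egressed-PC dynamics
  use expected-value decay.
- Absolute cell counts are not calibrated to cytometry; comparisons
  across arms/doses/gates are the meaningful outputs.
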