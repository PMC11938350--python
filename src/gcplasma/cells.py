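"""B-cell receptor genotypes, affinity evaluation and the cell agent."""

from __future__ import annotations

from dataclasses import dataclass

from .config import AffinityModel, HOTSPOT_MUTATIONS

GC_COMPARTMENTS = frozenset({"LZ", "DZ"})
COMPARTMENTS = frozenset({"LZ", "DZ", "prePC", "PC", "dead"})

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string (standard code, '*' = stop)."""
    return "".join(_CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


@dataclass(frozen=True)
class BcrGenotype:
    """Paired-chain receptor genotype.

    Mutations are identifier strings; hotspot substitutions use their
    canonical names (W33L/K59R/Y99G), neutral ones encode a codon position
    plus a unique serial so sets only ever grow along a lineage.  Junctions
    are fixed at clone founding and identify the clone.
    """

    germline_v_heavy: str
    germline_v_light: str
    junction_heavy: str
    junction_light: str
    mutations_heavy: frozenset[str] = frozenset()
    mutations_light: frozenset[str] = frozenset()

    def with_heavy(self, mutation: str) -> "BcrGenotype":
        return BcrGenotype(
            self.germline_v_heavy,
            self.germline_v_light,
            self.junction_heavy,
            self.junction_light,
            self.mutations_heavy | {mutation},
            self.mutations_light,
        )

    def with_light(self, mutation: str) -> "BcrGenotype":
        return BcrGenotype(
            self.germline_v_heavy,
            self.germline_v_light,
            self.junction_heavy,
            self.junction_light,
            self.mutations_heavy,
            self.mutations_light | {mutation},
        )

    @property
    def mutation_load(self) -> int:
        return len(self.mutations_heavy) + len(self.mutations_light)

    @property
    def hotspot_mutations(self) -> frozenset[str]:
        return self.mutations_heavy & frozenset(HOTSPOT_MUTATIONS)


def affinity_of(genotype: BcrGenotype, model: AffinityModel) -> float:
    """Affinity = germline baseline x product of acquired mutation factors.

    Neutral mutations are absent from ``model.mutation_effects`` and
    contribute a factor of 1.  Lethal mutations never reach this call:
    the cell dies when the mutation is drawn.
    """
    try:
        a = model.base_affinity_by_germline[genotype.germline_v_heavy]
    except KeyError:
        raise KeyError(
            f"unknown heavy germline {genotype.germline_v_heavy!r}; known: "
            f"{sorted(model.base_affinity_by_germline)}"
        ) from None
    for m in genotype.mutations_heavy | genotype.mutations_light:
        a *= model.mutation_effects.get(m, 1.0)
    return a


@dataclass(slots=True)
class Cell:
    """One agent.

    ``label_divisions`` counts divisions since doxycycline switched label
    synthesis off, so the division-dilution label is exactly
    ``L0 * 2**-label_divisions``.
    """

    id: int
    founder_id: int
    genotype: BcrGenotype
    compartment: str
    affinity: float
    parent_id: int | None = None
    myc: float = 0.0
    pending_divisions: int = 0
    division_count: int = 0
    label_s1pr2: bool = False
    label_blimp1: bool = False
    label_divisions: int = 0
    pc_division_count: int = 0
    alive: bool = True
    egressed: bool = False
    resident: bool = False
    residency_checked: bool = False
    prepc_age: int = 0

    def label_dilution(self, l0: float) -> float:
        return l0 * 2.0 ** (-self.label_divisions)
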