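"""Glycan compositions, structures and theoretical fragment ions.

An N-glycan is modelled as a rooted tree built from one of four core motifs
(the trimannosyl-chitobiose core HexNAc2Hex3, optionally core-fucosylated
and/or carrying a bisecting GlcNAc) plus a multiset of linear antenna
(branch) motifs drawn from a 12-motif library.  Compositions are written in
the N/H/F/S convention (e.g. ``N5H4F1S1`` = HexNAc5 Hex4 Fuc1 NeuAc1).

Fragment chemistry follows dual-energy HCD behaviour: B (oxonium) ions are
glycan fragments retaining the non-reducing end, observed at low collision
energy; Y ions retain the peptide plus a connected remnant of the glycan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, NamedTuple

import yaml

# Standard monoisotopic residue masses (Da).
RESIDUE_MASS = {
    "Hex": 162.052824,
    "HexNAc": 203.079373,
    "Fuc": 146.057909,
    "NeuAc": 291.095417,
}
PROTON = 1.007276
WATER = 18.010565

_CODE_TO_LETTER = {"HexNAc": "N", "Hex": "H", "Fuc": "F", "NeuAc": "S"}
_LETTER_TO_CODE = {v: k for k, v in _CODE_TO_LETTER.items()}

MAX_NON_MANNOSE_ANTENNAE = 4
MAX_BRANCHES = 6


class GlycanCompositionError(ValueError):
    pass


class Composition(NamedTuple):
    """Monosaccharide counts of a glycan or glycan fragment."""

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0

    def __add__(self, other: "Composition") -> "Composition":  # type: ignore[override]
        return Composition(*(a + b for a, b in zip(self, other)))

    def __sub__(self, other: "Composition") -> "Composition":
        return Composition(*(a - b for a, b in zip(self, other)))

    def is_nonnegative(self) -> bool:
        return all(c >= 0 for c in self)

    def total(self) -> int:
        return sum(self)

    @property
    def mass(self) -> float:
        return composition_mass(self)

    def serialize(self) -> str:
        return serialize_composition(self)


_CODE_TO_FIELD = {"HexNAc": 0, "Hex": 1, "Fuc": 2, "NeuAc": 3}


def comp_from_codes(codes: Iterable[str]) -> Composition:
    counts = [0, 0, 0, 0]
    for code in codes:
        if code not in _CODE_TO_FIELD:
            raise GlycanCompositionError(f"unknown monosaccharide code: {code!r}")
        counts[_CODE_TO_FIELD[code]] += 1
    return Composition(*counts)


def composition_mass(comp: Composition) -> float:
    """Neutral residue-mass sum of a composition (Da)."""
    if not comp.is_nonnegative():
        raise GlycanCompositionError(f"negative count in composition {comp}")
    return (
        comp.hexnac * RESIDUE_MASS["HexNAc"]
        + comp.hex * RESIDUE_MASS["Hex"]
        + comp.fuc * RESIDUE_MASS["Fuc"]
        + comp.neuac * RESIDUE_MASS["NeuAc"]
    )


def oxonium_mz(fragment: Composition, charge: int = 1) -> float:
    """m/z of a protonated B (oxonium) ion for a glycan fragment."""
    if fragment.total() == 0:
        raise GlycanCompositionError("oxonium ion requires a non-empty fragment")
    if charge < 1:
        raise GlycanCompositionError("charge must be >= 1")
    return (composition_mass(fragment) + charge * PROTON) / charge


def parse_composition(text: str) -> Composition:
    """Parse the N/H/F/S convention, e.g. ``"N5H4F1S1"``; absent terms are 0."""
    counts = {"N": 0, "H": 0, "F": 0, "S": 0}
    i = 0
    while i < len(text):
        letter = text[i]
        if letter not in counts:
            raise GlycanCompositionError(
                f"cannot parse {text!r}: unknown monosaccharide letter {letter!r}"
            )
        i += 1
        j = i
        while j < len(text) and text[j].isdigit():
            j += 1
        if j == i:
            raise GlycanCompositionError(f"cannot parse {text!r}: missing count after {letter!r}")
        counts[letter] += int(text[i:j])
        i = j
    return Composition(counts["N"], counts["H"], counts["F"], counts["S"])


def serialize_composition(comp: Composition) -> str:
    out = []
    for letter, count in zip("NHFS", comp):
        if count:
            out.append(f"{letter}{count}")
    return "".join(out) or "N0"


# ---------------------------------------------------------------------------
# Core and branch motifs


CORE_KINDS = ("plain", "core_fucosylated", "bisecting", "fucosylated_bisecting")

# Short core codes used in canonical structure strings.  Codes are chosen so
# that, under the engine's lexicographic tie-break between spectrally
# indistinguishable assemblies, a bisecting core is preferred over the
# equivalent "plain core + truncated GlcNAc antenna" reading of the same
# ion ladder.
CORE_CODE = {
    "plain": "C",
    "core_fucosylated": "CF",
    "bisecting": "CB",
    "fucosylated_bisecting": "CFB",
}
CODE_CORE = {v: k for k, v in CORE_CODE.items()}

_CORE_COMPOSITION = {
    "plain": Composition(2, 3, 0, 0),
    "core_fucosylated": Composition(2, 3, 1, 0),
    "bisecting": Composition(3, 3, 0, 0),
    "fucosylated_bisecting": Composition(3, 3, 1, 0),
}


def core_composition(kind: str) -> Composition:
    try:
        return _CORE_COMPOSITION[kind]
    except KeyError:
        raise GlycanCompositionError(f"unknown core kind: {kind!r}") from None


@dataclass(frozen=True)
class BranchMotif:
    """Linear antenna motif: residue chain root->terminus plus decorations."""

    name: str
    chain: tuple[str, ...]
    family: str  # GlcNAc | LacNAc | LacdiNAc | Mannose
    decorations: tuple[str, ...] = ()
    linkage: str = ""  # annotation only, never used in matching

    @property
    def composition(self) -> Composition:
        return comp_from_codes(self.chain) + comp_from_codes(self.decorations)

    def fragment_compositions(self) -> list[Composition]:
        """All B-ion sub-fragments: chain suffixes x decoration subsets.

        B ions retain the non-reducing end, so contiguous sub-fragments are
        suffixes of the root-ordered chain; terminal decorations may ride any
        suffix (they sit at the non-reducing end).
        """
        frags = set()
        for k in range(1, len(self.chain) + 1):
            suffix = comp_from_codes(self.chain[-k:])
            for r in range(len(self.decorations) + 1):
                for decs in itertools.combinations(self.decorations, r):
                    frags.add(suffix + comp_from_codes(decs))
        return sorted(frags)

    def prune_compositions(self) -> list[Composition]:
        """Retained-glycan options for Y ions: terminally pruned states.

        Options are the empty branch, each proper root prefix, and the full
        chain with any decoration subset (decorations are terminal, so a
        partial chain cannot retain them).
        """
        opts = {Composition()}
        for k in range(1, len(self.chain)):
            opts.add(comp_from_codes(self.chain[:k]))
        full = comp_from_codes(self.chain)
        for r in range(len(self.decorations) + 1):
            for decs in itertools.combinations(self.decorations, r):
                opts.add(full + comp_from_codes(decs))
        return sorted(opts)


@dataclass(frozen=True)
class BranchLibrary:
    motifs: tuple[BranchMotif, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("branch motif names must be unique")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def get(self, name: str) -> BranchMotif:
        for m in self.motifs:
            if m.name == name:
                return m
        raise KeyError(f"no branch motif named {name!r}")


def load_branch_library(path=None) -> BranchLibrary:
    """Load a branch library from YAML; default is the packaged 12-motif file."""
    if path is None:
        text = resources.files("glycosite").joinpath("branch_library.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    spec = yaml.safe_load(text)
    motifs = tuple(
        BranchMotif(
            name=entry["name"],
            chain=tuple(entry["chain"]),
            family=entry["family"],
            decorations=tuple(entry.get("decorations", ())),
            linkage=entry.get("linkage", ""),
        )
        for entry in spec["branches"]
    )
    return BranchLibrary(motifs)


@lru_cache(maxsize=1)
def default_library() -> BranchLibrary:
    return load_branch_library()


# ---------------------------------------------------------------------------
# Glycan structures


@dataclass(frozen=True)
class GlycanStructure:
    """Core motif plus a multiset of branch motifs.

    ``canonical`` is a branch-permutation-invariant text encoding
    (``core_kind|motif,motif,...`` with motif names sorted).
    """

    core: str
    branches: tuple[BranchMotif, ...]

    def __post_init__(self) -> None:
        core_composition(self.core)  # validates kind
        object.__setattr__(
            self, "branches", tuple(sorted(self.branches, key=lambda m: m.name))
        )

    @property
    def canonical(self) -> str:
        return f"{CORE_CODE[self.core]}|{','.join(m.name for m in self.branches)}"

    @property
    def composition(self) -> Composition:
        comp = core_composition(self.core)
        for m in self.branches:
            comp = comp + m.composition
        return comp

    @property
    def subtype(self) -> str:
        return classify_features(self).subtype

    @property
    def n_antennae(self) -> int:
        return sum(1 for m in self.branches if m.family != "Mannose")


def parse_structure(text: str, library: BranchLibrary | None = None) -> GlycanStructure:
    library = library or default_library()
    core, _, branch_part = text.partition("|")
    core = CODE_CORE.get(core, core)  # accept either code or full kind name
    names = [n for n in branch_part.split(",") if n]
    return GlycanStructure(core, tuple(library.get(n) for n in names))


def structure_to_composition(structure: GlycanStructure) -> Composition:
    return structure.composition


def enumerate_structures(
    comp: Composition, library: BranchLibrary | None = None
) -> list[GlycanStructure]:
    """All library structures whose composition equals ``comp`` exactly.

    Bounded by the antenna cap (<= 4 non-mannose antennae) and a total
    branch cap of 6; compositions smaller than every core give an empty list.
    """
    library = library or default_library()
    out: dict[str, GlycanStructure] = {}
    motifs = sorted(library, key=lambda m: m.name)
    for kind in CORE_KINDS:
        residual = comp - core_composition(kind)
        if not residual.is_nonnegative():
            continue
        for multiset in _branch_multisets(residual, motifs):
            s = GlycanStructure(kind, multiset)
            out[s.canonical] = s
    return [out[k] for k in sorted(out)]


def _branch_multisets(
    residual: Composition, motifs: list[BranchMotif]
) -> Iterable[tuple[BranchMotif, ...]]:
    """Backtracking enumeration of motif multisets summing exactly to residual."""

    def rec(remaining: Composition, start: int, chosen: list[BranchMotif], n_ant: int):
        if remaining.total() == 0:
            yield tuple(chosen)
            return
        if len(chosen) >= MAX_BRANCHES:
            return
        for i in range(start, len(motifs)):
            m = motifs[i]
            nxt = remaining - m.composition
            if not nxt.is_nonnegative():
                continue
            ant = n_ant + (m.family != "Mannose")
            if ant > MAX_NON_MANNOSE_ANTENNAE:
                continue
            chosen.append(m)
            yield from rec(nxt, i, chosen, ant)
            chosen.pop()

    yield from rec(residual, 0, [], 0)


# ---------------------------------------------------------------------------
# Theoretical fragment ions


def theoretical_B_ions(
    structure: GlycanStructure, mass_shift_per_branch: float = 0.0
) -> list[tuple[Composition, float]]:
    """Singly protonated B (oxonium) ions of a structure.

    Includes the single-residue oxonium of every residue type present, and
    for every branch all contiguous sub-fragments retaining the non-reducing
    terminus.  A LacdiNAc branch therefore always yields a HexNAc2 B ion.
    ``mass_shift_per_branch`` shifts every branch-derived fragment mass; used
    to build decoy structural hypotheses.
    """
    frags: dict[Composition, float] = {}
    comp = structure.composition
    for code, idx in _CODE_TO_FIELD.items():
        if comp[idx] > 0:
            c = comp_from_codes([code])
            frags[c] = composition_mass(c)
    for m in structure.branches:
        for frag in m.fragment_compositions():
            mass = composition_mass(frag) + mass_shift_per_branch
            if frag not in frags or mass_shift_per_branch:
                frags[frag] = mass
    ions = [(c, mass + PROTON) for c, mass in frags.items()]
    ions.sort(key=lambda t: t[1])
    return ions


def _core_retained(structure: GlycanStructure) -> set[tuple[Composition, int]]:
    """Retained (composition, n-branch-motifs) states of the core ladder."""
    ladder = [
        Composition(),
        Composition(1, 0, 0, 0),
        Composition(2, 0, 0, 0),
        Composition(2, 1, 0, 0),
        Composition(2, 2, 0, 0),
        Composition(2, 3, 0, 0),
    ]
    states = set(ladder)
    if structure.core in ("core_fucosylated", "fucosylated_bisecting"):
        # core Fuc sits on the innermost GlcNAc: retained whenever >= Y1
        states |= {c + Composition(0, 0, 1, 0) for c in ladder[1:]}
    if structure.core in ("bisecting", "fucosylated_bisecting"):
        bis = {c + Composition(1, 0, 0, 0) for c in states if c.hex == 3}
        states |= bis
    return {(c, 0) for c in states}


def theoretical_Y_ions(
    structure: GlycanStructure,
    peptide_mass: float,
    charges: Iterable[int] = (1,),
    mass_shift_per_branch: float = 0.0,
) -> list[tuple[Composition, int, float]]:
    """Y ions: peptide plus every connected, terminally pruned glycan remnant.

    Includes Y0 (bare peptide), Y1 (peptide+HexNAc), the core ladder with
    Fuc/bisecting variants where applicable, and the full core combined with
    every per-branch pruning option.  m/z = (peptide + glycan + z*proton)/z.
    """
    if peptide_mass <= 0:
        raise ValueError("peptide mass must be positive")
    charges = sorted(set(charges))
    if any(z < 1 or z > 4 for z in charges):
        raise ValueError("Y-ion charges must lie in 1..4")

    retained: dict[Composition, float] = {}
    for comp, _ in _core_retained(structure):
        retained.setdefault(comp, composition_mass(comp))

    full_cores = [core_composition(structure.core)]
    if structure.core in ("bisecting", "fucosylated_bisecting"):
        # bisecting GlcNAc may itself be lost before the branches are
        full_cores.append(core_composition(structure.core) - Composition(1, 0, 0, 0))
    branch_opts = [m.prune_compositions() for m in structure.branches]
    for core_c in full_cores:
        for combo in itertools.product(*branch_opts):
            comp = core_c
            n_kept = 0
            for c in combo:
                comp = comp + c
                n_kept += c.total() > 0
            mass = composition_mass(comp) + mass_shift_per_branch * n_kept
            if comp not in retained or mass_shift_per_branch:
                retained[comp] = mass
    ions = []
    for comp, gmass in retained.items():
        for z in charges:
            mz = (peptide_mass + gmass + z * PROTON) / z
            ions.append((comp, z, mz))
    ions.sort(key=lambda t: t[2])
    return ions


# ---------------------------------------------------------------------------
# Structural feature classification


@dataclass(frozen=True)
class FeatureVector:
    subtype: str
    core_kind: str
    n_fucose: int
    n_sialic: int
    n_antennae: int
    has_lacdinac: bool
    has_core_fucose: bool
    has_bisecting: bool
    antenna_fucose: bool
    branch_families: tuple[str, ...] = ()


def classify_features(structure: GlycanStructure) -> FeatureVector:
    """Derive the structural feature vector used for frequency summaries.

    Subtype: oligo-mannose if every branch is mannose-family with no
    bisecting GlcNAc; complex if every antenna is HexNAc-initiated; hybrid
    otherwise (mixed Hex- and HexNAc-initiated antennae).
    """
    comp = structure.composition
    branches = structure.branches
    hexnac_initiated = [m for m in branches if m.chain[0] == "HexNAc"]
    hex_initiated = [m for m in branches if m.chain[0] == "Hex"]
    bisecting = structure.core in ("bisecting", "fucosylated_bisecting")
    if not hexnac_initiated and not bisecting:
        subtype = "oligo_mannose"
    elif not hex_initiated:
        subtype = "complex"
    else:
        subtype = "hybrid"
    return FeatureVector(
        subtype=subtype,
        core_kind=structure.core,
        n_fucose=comp.fuc,
        n_sialic=comp.neuac,
        n_antennae=structure.n_antennae,
        has_lacdinac=any(m.family == "LacdiNAc" for m in branches),
        has_core_fucose=structure.core in ("core_fucosylated", "fucosylated_bisecting"),
        has_bisecting=bisecting,
        antenna_fucose=any("Fuc" in m.decorations for m in branches),
        branch_families=tuple(sorted({m.family for m in branches})),
    )
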