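"""Glycosite-restricted peptide search space from a protein FASTA.

Tryptic digestion (cleave C-terminal to K/R except before P, up to two
missed cleavages), N-glycosylation sequon detection (N-X-S/T, X != P,
resolved against full-protein context so sequons spanning the peptide
C-terminus are handled), static/variable modifications, and pseudo-reverse
decoys (sequence reversed keeping the C-terminal residue, which preserves
tryptic mass and charge properties).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from pyteomics import fasta as _fasta
from pyteomics import mass as _pmass

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Modification deltas (Da)
CARBAMIDOMETHYL = 57.021464
TMT10 = 229.162932
OXIDATION = 15.9949
ACETYL = 42.010565

_SEQUON_RE = re.compile(r"(?=(N[^P][ST]))")


class DigestError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideCandidate:
    protein_id: str
    sequence: str
    start: int  # 1-based inclusive protein coordinates
    end: int
    missed_cleavages: int
    sequon_positions: tuple[int, ...]  # protein coordinates of sequon N
    neutral_mass: float = 0.0
    is_decoy: bool = False

    @property
    def peptide_sequon_offsets(self) -> tuple[int, ...]:
        """Sequon positions as 0-based offsets within the peptide."""
        return tuple(p - self.start for p in self.sequon_positions)


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices after which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def find_sequons(peptide: str, protein_offset: int = 1, context: str = "") -> tuple[int, ...]:
    """Protein coordinates of N-X-S/T (X != P) sequon asparagines.

    ``context`` is the protein sequence following the peptide, so motifs
    whose S/T falls beyond the peptide C-terminus are still detected.
    """
    if not peptide:
        return ()
    window = peptide + context[:2]
    return tuple(
        protein_offset + m.start()
        for m in _SEQUON_RE.finditer(window)
        if m.start() < len(peptide)
    )


def digest(
    protein_id: str,
    sequence: str,
    max_missed: int = 2,
    min_length: int = 1,
    max_length: int = 10**9,
) -> list[PeptideCandidate]:
    """All tryptic products with 0..max_missed missed cleavages."""
    bad = [i for i, aa in enumerate(sequence) if aa not in AMINO_ACIDS]
    if bad:
        raise DigestError(
            f"{protein_id}: non-amino-acid character {sequence[bad[0]]!r} at position {bad[0] + 1}"
        )
    sites = cleavage_sites(sequence)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    out = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            pep = sequence[start:end]
            if not (min_length <= len(pep) <= max_length):
                continue
            out.append(
                PeptideCandidate(
                    protein_id=protein_id,
                    sequence=pep,
                    start=start + 1,
                    end=end,
                    missed_cleavages=missed,
                    sequon_positions=find_sequons(pep, start + 1, sequence[end:]),
                )
            )
    return out


def peptide_neutral_mass(
    sequence: str,
    tmt: bool = True,
    tmt_on_lysine: bool = True,
    carbamidomethyl: bool = True,
    variable_mods: dict[str, float] | None = None,
) -> float:
    """Monoisotopic neutral peptide mass with static/variable modifications.

    TMT labels every peptide N-terminus and (by default) every lysine;
    carbamidomethylation applies to every cysteine.  ``variable_mods`` maps
    a modification name to its delta and is summed in as given.
    """
    mass = _pmass.fast_mass(sequence)
    if carbamidomethyl:
        mass += CARBAMIDOMETHYL * sequence.count("C")
    if tmt:
        mass += TMT10
        if tmt_on_lysine:
            mass += TMT10 * sequence.count("K")
    for name, delta in (variable_mods or {}).items():
        if name not in ("oxidation", "acetyl", "tmt_k"):
            raise ValueError(f"unknown modification: {name!r}")
        mass += delta
    return mass


def pseudo_reverse(sequence: str, fixed: tuple[int, ...] = ()) -> str:
    """Reverse the sequence keeping the C-terminal residue in place.

    Positions in ``fixed`` (0-based) additionally stay put and the remaining
    residues are reversed among the free slots; used to preserve a sequon
    motif so that glycopeptide decoys stay inside the sequon-restricted
    search space and provide genuine score competition.
    """
    if len(sequence) < 2:
        return sequence
    keep = set(fixed) | {len(sequence) - 1}
    free = [i for i in range(len(sequence)) if i not in keep]
    out = list(sequence)
    for slot, src in zip(free, reversed(free)):
        out[slot] = sequence[src]
    return "".join(out)


def make_decoys(
    candidates: list[PeptideCandidate], preserve_sequon: bool = False
) -> list[PeptideCandidate]:
    """Pseudo-reverse decoy for every target; sequons re-evaluated.

    With ``preserve_sequon`` the first sequon triplet is pinned in place so
    every sequon-bearing target yields a sequon-bearing decoy.
    """
    decoys = []
    for c in candidates:
        fixed: tuple[int, ...] = ()
        if preserve_sequon and c.sequon_positions:
            p = c.peptide_sequon_offsets[0]
            fixed = tuple(q for q in (p, p + 1, p + 2) if q < len(c.sequence))
        seq = pseudo_reverse(c.sequence, fixed)
        decoys.append(
            replace(
                c,
                protein_id=f"decoy_{c.protein_id}",
                sequence=seq,
                sequon_positions=find_sequons(seq, c.start),
                is_decoy=True,
                neutral_mass=c.neutral_mass,
            )
        )
    return decoys


def read_fasta(path) -> list[tuple[str, str]]:
    """(accession, sequence) pairs; UniProt-style pipe headers supported."""
    entries = []
    with _fasta.read(str(path)) as reader:
        for header, seq in reader:
            fields = header.split("|")
            acc = fields[1] if len(fields) >= 2 else header.split()[0]
            entries.append((acc, seq))
    return entries


def write_fasta(entries: list[tuple[str, str]], path) -> None:
    _fasta.write(
        [(acc, seq) for acc, seq in entries], str(path), file_mode="w"
    )


@dataclass
class SearchSpace:
    """Indexed peptide candidates for precursor-mass lookup."""

    glyco: list[PeptideCandidate]  # sequon-bearing targets + decoys
    proteome: list[PeptideCandidate]  # all targets + decoys, no sequon filter


def build_search_space(
    entries: list[tuple[str, str]],
    max_missed: int = 2,
    min_length: int = 6,
    max_length: int = 45,
    min_mass: float = 600.0,
    max_mass: float = 6000.0,
    with_decoys: bool = True,
) -> SearchSpace:
    targets: list[PeptideCandidate] = []
    seen = set()
    for acc, seq in entries:
        for cand in digest(acc, seq, max_missed, min_length, max_length):
            key = (acc, cand.start, cand.end)
            if key in seen:
                continue
            seen.add(key)
            m = peptide_neutral_mass(cand.sequence)
            if not (min_mass <= m <= max_mass):
                continue
            targets.append(replace(cand, neutral_mass=m))
    decoys = make_decoys(targets, preserve_sequon=True) if with_decoys else []
    candidates = targets + decoys
    glyco = [c for c in candidates if c.sequon_positions]
    return SearchSpace(glyco=glyco, proteome=candidates)


def b_y_ions(
    sequence: str,
    tmt: bool = True,
    tmt_on_lysine: bool = True,
    carbamidomethyl: bool = True,
    charges: tuple[int, ...] = (1,),
) -> list[tuple[str, int, float]]:
    """Backbone b/y fragment ions of the (TMT-labelled) peptide.

    The glycan is assumed lost from backbone fragments (high-energy HCD
    strips it), so the glycosylated asparagine carries no extra mass here.
    """
    n = len(sequence)
    prefix = [0.0]
    for aa in sequence:
        delta = _pmass.std_aa_mass[aa]
        if aa == "C" and carbamidomethyl:
            delta += CARBAMIDOMETHYL
        if aa == "K" and tmt and tmt_on_lysine:
            delta += TMT10
        prefix.append(prefix[-1] + delta)
    nterm = TMT10 if tmt else 0.0
    total = prefix[n]
    ions = []
    for i in range(1, n):
        b_neutral = nterm + prefix[i]  # b ion: residues minus OH (no water)
        y_neutral = total - prefix[i] + _pmass.calculate_mass(formula="H2O")
        for z in charges:
            ions.append((f"b{i}", z, (b_neutral + z * 1.007276) / z))
            ions.append((f"y{n - i}", z, (y_neutral + z * 1.007276) / z))
    ions.sort(key=lambda t: t[2])
    return ions
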