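"""Mass arithmetic for proteins, tryptic peptides and MS/MS fragment ions.

Everything here is plain residue-mass bookkeeping: neutral peptide masses
(monoisotopic or average), in-silico tryptic digestion with missed-cleavage
enumeration, singly protonated b/y/a fragment ions, and the nominal mass
shifts produced by iodoacetamide carbamidomethylation (+57 Da per cysteine,
+160 Da for the CAM-Cys residue gap read off a fragment ladder).

All ``*_mass`` functions return neutral masses; only :func:`fragment_ions`
returns [M+H]+ m/z values, matching singly charged MALDI spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

MassMode = Literal["mono", "avg"]

#: (monoisotopic, average) residue masses in Da for the 20 standard amino acids.
RESIDUE_MASSES: dict[str, tuple[float, float]] = {
    "G": (57.02146, 57.0513),
    "A": (71.03711, 71.0779),
    "S": (87.03203, 87.0773),
    "P": (97.05276, 97.1152),
    "V": (99.06841, 99.1311),
    "T": (101.04768, 101.1039),
    "C": (103.00919, 103.1429),
    "L": (113.08406, 113.1576),
    "I": (113.08406, 113.1576),
    "N": (114.04293, 114.1026),
    "D": (115.02694, 115.0874),
    "Q": (128.05858, 128.1292),
    "K": (128.09496, 128.1723),
    "E": (129.04259, 129.1140),
    "M": (131.04049, 131.1961),
    "H": (137.05891, 137.1393),
    "F": (147.06841, 147.1739),
    "R": (156.10111, 156.1857),
    "Y": (163.06333, 163.1733),
    "W": (186.07931, 186.2099),
}

WATER_MONO = 18.01056
WATER_AVG = 18.0153
PROTON = 1.00728
#: CO loss distinguishing a-ions from b-ions (monoisotopic).
CO_MONO = 27.99491
#: Mass removed by forming an internal disulfide from two free thiols (2 H).
DISULFIDE_DELTA_MONO = 2.01565


class UnknownResidueError(KeyError):
    """Raised when a sequence contains a non-standard one-letter code."""


@dataclass(frozen=True)
class Modification:
    """A fixed post-translational modification with its mass deltas."""

    name: str
    delta_mono: float
    delta_avg: float
    target: str

    def delta(self, mode: MassMode) -> float:
        return self.delta_mono if mode == "mono" else self.delta_avg


#: Carbamidomethylation of cysteine by iodoacetamide (S-CH2-CONH2).
CAM = Modification("CAM", 57.02146, 57.0513, "C")

_MODS = {"CAM": CAM}


def get_modification(name: str) -> Modification:
    try:
        return _MODS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown modification {name!r}; known: {sorted(_MODS)}") from None


@dataclass(frozen=True)
class PeptideSpan:
    """A peptide located in its parent protein.

    ``start``/``end`` are 1-based inclusive positions in the parent sequence.
    ``mods`` maps 1-based positions *within the peptide* to modifications.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0
    mods: dict[int, Modification] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"span length mismatch: len({self.sequence!r}) != {self.end}-{self.start}+1"
            )
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        for pos in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside peptide")

    def with_mods(self, mods: dict[int, Modification]) -> "PeptideSpan":
        return PeptideSpan(self.sequence, self.start, self.end, self.missed_cleavages, dict(mods))


def _residue_mass(code: str, mode: MassMode) -> float:
    try:
        mono, avg = RESIDUE_MASSES[code]
    except KeyError:
        raise UnknownResidueError(f"unknown residue code {code!r}") from None
    return mono if mode == "mono" else avg


def peptide_mass(span: PeptideSpan | str, mode: MassMode = "mono") -> float:
    """Neutral mass of a (possibly modified) peptide in Da.

    Sum of residue masses plus one water plus any modification deltas.
    """
    if isinstance(span, str):
        span = PeptideSpan(span, 1, len(span))
    total = WATER_MONO if mode == "mono" else WATER_AVG
    for code in span.sequence:
        total += _residue_mass(code, mode)
    for mod in span.mods.values():
        total += mod.delta(mode)
    return total


def digest_tryptic(
    protein_sequence: str,
    max_missed: int = 0,
    keil_rule: bool = True,
) -> list[PeptideSpan]:
    """In-silico tryptic digest: cleave C-terminal to K or R.

    With ``keil_rule`` (default) a K/R followed by proline is not cleaved,
    which is what keeps the WCGPC active-site peptide intact. Peptides with
    0..``max_missed`` missed cleavages are all returned; the zero-missed
    peptides tile the protein exactly.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    for code in protein_sequence:
        if code not in RESIDUE_MASSES:
            raise UnknownResidueError(f"unknown residue code {code!r}")
    n = len(protein_sequence)
    # cut sites: index i means a cut between position i and i+1 (0-based)
    cuts = [0]
    for i in range(n - 1):
        if protein_sequence[i] in "KR":
            if keil_rule and protein_sequence[i + 1] == "P":
                continue
            cuts.append(i + 1)
    cuts.append(n)
    spans: list[PeptideSpan] = []
    for a in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            seq = protein_sequence[cuts[a] : cuts[b]]
            spans.append(PeptideSpan(seq, cuts[a] + 1, cuts[b], missed))
    return spans


def fragment_ions(
    span: PeptideSpan | str,
    series: Iterable[str] = ("b", "y"),
    mode: MassMode = "mono",
) -> list[tuple[str, float]]:
    """Singly protonated a/b/y fragment-ion m/z values for a peptide.

    b_i keeps the N-terminal i residues (+ proton); y_j keeps the C-terminal
    j residues (+ water + proton); a_i = b_i - CO. Labels carry an asterisk
    when the fragment contains a modified residue (e.g. ``y*5``), following
    the usual annotation convention for carbamidomethylated fragments.
    Indices run 1..len-1: the full-length "fragment" is not emitted.
    """
    if isinstance(span, str):
        span = PeptideSpan(span, 1, len(span))
    series = list(series)
    if not series:
        raise ValueError("series must be non-empty")
    bad = set(series) - {"a", "b", "y"}
    if bad:
        raise ValueError(f"unknown ion series {sorted(bad)}")
    seq = span.sequence
    n = len(seq)
    water = WATER_MONO if mode == "mono" else WATER_AVG
    res = [_residue_mass(c, mode) for c in seq]
    for pos, mod in span.mods.items():
        res[pos - 1] += mod.delta(mode)
    modded = [pos - 1 for pos in span.mods]

    out: list[tuple[str, float]] = []
    # prefix sums for b/a ions, suffix sums for y ions
    prefix = 0.0
    for i in range(1, n):
        prefix += res[i - 1]
        star = "*" if any(p < i for p in modded) else ""
        if "b" in series:
            out.append((f"b{star}{i}", prefix + PROTON))
        if "a" in series:
            out.append((f"a{star}{i}", prefix + PROTON - CO_MONO))
    suffix = 0.0
    for j in range(1, n):
        suffix += res[n - j]
        star = "*" if any(p >= n - j for p in modded) else ""
        if "y" in series:
            out.append((f"y{star}{j}", suffix + water + PROTON))
    return out


def cam_residue_gap(mode: MassMode = "mono") -> float:
    """Residue mass of carbamidomethyl-cysteine (the fragment-ladder gap).

    A 160 Da (nominal) spacing between consecutive y or b ions pins the
    alkylation site to that cysteine; an unmodified Cys gap is 103 Da.
    """
    return _residue_mass("C", mode) + CAM.delta(mode)


def nominal(mass: float) -> int:
    """Integer nominal mass: round half away from zero."""
    return int(math.floor(abs(mass) + 0.5)) * (1 if mass >= 0 else -1)


def species_mass(
    base_mass: float,
    n_cam: int,
    mode: MassMode = "avg",
    disulfide: bool = False,
) -> float:
    """Mass of the intact protein carrying ``n_cam`` carbamidomethyl groups.

    ``disulfide=True`` subtracts 2 H for an internal disulfide (oxidized
    protein); the default models the reduced / alkylated species.
    """
    if n_cam < 0:
        raise ValueError("n_cam must be >= 0")
    mass = base_mass + n_cam * CAM.delta(mode)
    if disulfide:
        mass -= DISULFIDE_DELTA_MONO
    return mass


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (header, sequence) pairs from a plain FASTA file."""
    records: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].strip()
                chunks = []
            else:
                chunks.append(line.upper())
    if header is not None:
        records.append((header, "".join(chunks)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
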