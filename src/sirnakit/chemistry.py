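"""Modified oligonucleotide strand and construct chemistry.

Strands are fully chemically modified: every position carries a sugar
chemistry (ribo, 2'-O-methyl, or 2'-fluoro) and every internal linkage
is phosphodiester (PO) or phosphorothioate (PS).  Constructs are either
monovalent duplexes (optionally cholesterol-conjugated on the passenger
3' end) or divalent constructs: two identical duplexes whose passenger
3' ends are joined by a tetraethylene glycol branch.

A compact per-position text grammar encodes a strand: one token per
nucleotide, ``<sugar><base><linkage>``, where sugar is ``m`` (2'-OMe),
``f`` (2'-F) or ``r`` (ribo), base is one of ``ACGU`` (``T`` accepted as
``U``), and a trailing ``#`` marks a phosphorothioate linkage to the
next nucleotide.  Whitespace between tokens is ignored.  Example:
``mU# fU# mA fU ... mU`` is a 5'-terminal pair of PS linkages followed
by an alternating OMe/F body.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .transcript_model import reverse_complement

SUGARS = {"ribo", "2OMe", "2F"}
_SUGAR_CODE = {"m": "2OMe", "f": "2F", "r": "ribo"}
_CODE_SUGAR = {v: k for k, v in _SUGAR_CODE.items()}
FIVE_PRIME_GROUPS = {"OH", "phosphate", "vinylphosphonate"}
THREE_PRIME_GROUPS = {"OH", "cholesterol_TEG", "linker_attachment"}

_TOKEN_RE = re.compile(r"([mfr])([ACGUTacgut])(#?)")

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ModifiedNucleotide:
    base: str
    sugar: str
    linkage_to_next: str  # "PO", "PS", or "none" for the 3'-terminal position

    def __post_init__(self) -> None:
        if self.base not in "ACGU":
            raise ValueError(f"invalid base {self.base!r}")
        if self.sugar not in SUGARS:
            raise ValueError(f"invalid sugar {self.sugar!r}")
        if self.linkage_to_next not in {"PO", "PS", "none"}:
            raise ValueError(f"invalid linkage {self.linkage_to_next!r}")


@dataclass
class ModifiedStrand:
    """One strand with per-position chemistry and terminal groups."""

    role: str  # "guide" or "passenger"
    nucleotides: list[ModifiedNucleotide]
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        if self.role not in {"guide", "passenger"}:
            raise ValueError(f"invalid role {self.role!r}")
        if not self.nucleotides:
            raise ValueError("empty strand")
        if self.nucleotides[-1].linkage_to_next != "none":
            raise ValueError("3'-terminal nucleotide must have linkage 'none'")
        if any(n.linkage_to_next == "none" for n in self.nucleotides[:-1]):
            raise ValueError("internal nucleotide with linkage 'none'")
        if self.five_prime not in FIVE_PRIME_GROUPS:
            raise ValueError(f"invalid 5' group {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_GROUPS:
            raise ValueError(f"invalid 3' group {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def sequence(self) -> str:
        return "".join(n.base for n in self.nucleotides)

    def count_sugar(self, sugar: str) -> int:
        return sum(1 for n in self.nucleotides if n.sugar == sugar)

    def count_ps(self) -> int:
        return sum(1 for n in self.nucleotides if n.linkage_to_next == "PS")

    def to_grammar(self) -> str:
        tokens = []
        for n in self.nucleotides:
            ps = "#" if n.linkage_to_next == "PS" else ""
            tokens.append(f"{_CODE_SUGAR[n.sugar]}{n.base}{ps}")
        return " ".join(tokens)


def parse_strand(
    grammar: str,
    role: str,
    five_prime: str = "OH",
    three_prime: str = "OH",
) -> ModifiedStrand:
    """Parse the per-position strand grammar into a :class:`ModifiedStrand`."""
    compact = "".join(grammar.split())
    nucleotides: list[ModifiedNucleotide] = []
    pos = 0
    while pos < len(compact):
        m = _TOKEN_RE.match(compact, pos)
        if m is None:
            raise ValueError(
                f"cannot parse strand grammar at {compact[pos:pos + 4]!r} "
                f"(offset {pos})"
            )
        sugar, base, ps = m.groups()
        base = base.upper().replace("T", "U")
        nucleotides.append(
            ModifiedNucleotide(
                base=base,
                sugar=_SUGAR_CODE[sugar],
                linkage_to_next="PS" if ps else "PO",
            )
        )
        pos = m.end()
    if nucleotides and nucleotides[-1].linkage_to_next == "PS":
        raise ValueError("3'-terminal nucleotide cannot carry a linkage (#)")
    if nucleotides:
        nucleotides[-1] = ModifiedNucleotide(
            nucleotides[-1].base, nucleotides[-1].sugar, "none"
        )
    return ModifiedStrand(
        role=role,
        nucleotides=nucleotides,
        five_prime=five_prime,
        three_prime=three_prime,
    )


@dataclass
class DuplexConstruct:
    """A monovalent duplex or a divalent two-duplex construct.

    Divalent constructs store one guide/passenger pattern; both copies
    are identical, so strand multiplicity is 2.
    """

    form: str  # "monovalent" or "divalent"
    guide: ModifiedStrand
    passenger: ModifiedStrand
    linker: str = "none"
    name: str = ""

    def __post_init__(self) -> None:
        if self.form not in {"monovalent", "divalent"}:
            raise ValueError(f"invalid form {self.form!r}")
        if self.form == "divalent" and self.linker == "none":
            raise ValueError("divalent construct requires a linker")
        if self.form == "monovalent" and self.linker != "none":
            raise ValueError("monovalent construct cannot have a linker")
        for strand in (self.guide, self.passenger):
            if len(strand) < 10:
                raise ValueError(
                    f"{strand.role} strand shorter than 10 nt"
                )
        report = validate_duplex(self.guide, self.passenger)
        if not report.valid:
            raise ValueError(
                f"guide/passenger not complementary: mismatches at guide "
                f"positions {report.mismatch_positions}"
            )

    @property
    def multiplicity(self) -> int:
        return 2 if self.form == "divalent" else 1

    def strands(self) -> list[tuple[ModifiedStrand, int]]:
        """(strand, copy count) pairs for the whole construct."""
        return [(self.guide, self.multiplicity),
                (self.passenger, self.multiplicity)]


@dataclass
class DuplexReport:
    valid: bool
    n_paired: int
    n_mismatches: int
    mismatch_positions: list[int]  # 1-based guide positions
    guide_overhang: int


def validate_duplex(
    guide: ModifiedStrand | str, passenger: ModifiedStrand | str
) -> DuplexReport:
    """Check Watson-Crick complementarity of a guide/passenger pair.

    The passenger anneals to the guide 5' region; a guide 3' overhang
    (asymmetric scaffold) is permitted.  Guide position i (1-based,
    from the guide 5' end) pairs with passenger position L_p - i + 1.
    """
    gseq = guide.sequence if isinstance(guide, ModifiedStrand) else guide
    pseq = passenger.sequence if isinstance(passenger, ModifiedStrand) else passenger
    if len(pseq) > len(gseq):
        raise ValueError("passenger longer than guide is not supported")
    mismatches = []
    for i in range(len(pseq)):
        if (gseq[i], pseq[len(pseq) - 1 - i]) not in _WC:
            mismatches.append(i + 1)
    return DuplexReport(
        valid=not mismatches,
        n_paired=len(pseq) - len(mismatches),
        n_mismatches=len(mismatches),
        mismatch_positions=mismatches,
        guide_overhang=len(gseq) - len(pseq),
    )


# ---------------------------------------------------------------------------
# Mass table


@dataclass(frozen=True)
class MassTable:
    """Average monomer/delta masses (g/mol) for strand assembly."""

    residues: dict[str, float]
    sugar_deltas: dict[str, float]
    ps_delta: float
    water: float
    five_prime: dict[str, float]
    three_prime: dict[str, float]
    linkers: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.residues.values()):
            raise ValueError("residue masses must be positive")


def load_mass_table() -> MassTable:
    """Load the packaged average-mass table."""
    path = importlib.resources.files("sirnakit.data") / "mass_table.tsv"
    table = pd.read_csv(path, sep="\t", comment="#")
    groups: dict[str, dict[str, float]] = {}
    for row in table.itertuples():
        groups.setdefault(row.kind, {})[row.key] = float(row.value)
    return MassTable(
        residues=groups["residue"],
        sugar_deltas=groups["sugar_delta"],
        ps_delta=groups["linkage_delta"]["PS"],
        water=groups["terminal"]["water"],
        five_prime=groups["five_prime"],
        three_prime=groups["three_prime"],
        linkers=groups["linker"],
    )


def strand_mass(strand: ModifiedStrand, mass_table: MassTable) -> float:
    """Average mass of one strand including terminal groups."""
    total = 0.0
    for pos, n in enumerate(strand.nucleotides, start=1):
        if n.base not in mass_table.residues:
            raise KeyError(f"no residue mass for base {n.base!r} at position {pos}")
        if n.sugar not in mass_table.sugar_deltas:
            raise KeyError(f"no sugar delta for {n.sugar!r} at position {pos}")
        total += mass_table.residues[n.base] + mass_table.sugar_deltas[n.sugar]
    total += strand.count_ps() * mass_table.ps_delta
    total += mass_table.water
    total += mass_table.five_prime[strand.five_prime]
    total += mass_table.three_prime[strand.three_prime]
    return total


def average_mass(
    construct: DuplexConstruct, mass_table: Optional[MassTable] = None
) -> float:
    """Average mass (g/mol) of the whole construct.

    Divalent constructs sum two copies of each strand plus the branching
    linker; the linker-attachment condensation correction is carried by
    the passenger 3' terminal group.
    """
    table = mass_table or load_mass_table()
    total = sum(strand_mass(s, table) * mult for s, mult in construct.strands())
    total += table.linkers[construct.linker]
    return total


def dose_mass(
    amount_nmol: float,
    construct: DuplexConstruct,
    mass_table: Optional[MassTable] = None,
) -> float:
    """Convert a molar dose (nmol) to mass (micrograms)."""
    if amount_nmol < 0:
        raise ValueError("amount_nmol must be >= 0")
    return amount_nmol * average_mass(construct, mass_table) * 1e-3


def modification_fractions(construct: DuplexConstruct) -> dict[str, float]:
    """Modification content of a construct, as percentages.

    Sugar percentages (``2OMe``, ``2F``, ``ribo``) are over all
    nucleotide positions of all strands; ``PS_linkage`` is over all
    internal linkages.  Raw fractions are exposed under ``*_fraction``.
    """
    n_positions = 0
    counts = {s: 0 for s in SUGARS}
    n_linkages = 0
    n_ps = 0
    for strand, mult in construct.strands():
        n_positions += len(strand) * mult
        for sugar in SUGARS:
            counts[sugar] += strand.count_sugar(sugar) * mult
        n_linkages += (len(strand) - 1) * mult
        n_ps += strand.count_ps() * mult
    out: dict[str, float] = {}
    for sugar in ("2OMe", "2F", "ribo"):
        frac = counts[sugar] / n_positions
        out[sugar] = round(100 * frac)
        out[f"{sugar}_fraction"] = frac
    out["PS_linkage"] = round(100 * n_ps / n_linkages)
    out["PS_linkage_fraction"] = n_ps / n_linkages
    return out


# ---------------------------------------------------------------------------
# Construct I/O


def _strand_from_config(cfg: dict, role: str) -> ModifiedStrand:
    return parse_strand(
        cfg["strand"],
        role=role,
        five_prime=cfg.get("five_prime", "OH"),
        three_prime=cfg.get("three_prime", "OH"),
    )


def load_construct(path: str | Path) -> DuplexConstruct:
    """Load a construct from a YAML file (strand grammar + termini + form)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return DuplexConstruct(
        form=cfg["form"],
        guide=_strand_from_config(cfg["guide"], "guide"),
        passenger=_strand_from_config(cfg["passenger"], "passenger"),
        linker=cfg.get("linker", "none"),
        name=cfg.get("name", Path(path).stem),
    )


def packaged_construct(name: str) -> DuplexConstruct:
    """Load one of the constructs shipped with the package by name."""
    path = importlib.resources.files("sirnakit.data") / "constructs" / f"{name}.yaml"
    with importlib.resources.as_file(path) as p:
        return load_construct(p)


def packaged_construct_names() -> list[str]:
    base = importlib.resources.files("sirnakit.data") / "constructs"
    return sorted(p.name.removesuffix(".yaml")
                  for p in base.iterdir() if p.name.endswith(".yaml"))


def construct_report(
    construct: DuplexConstruct,
    doses_nmol: tuple[float, ...] = (1.0, 12.5),
    mass_table: Optional[MassTable] = None,
) -> dict:
    """Summary dict: fractions, mass, per-dose masses, duplex check."""
    table = mass_table or load_mass_table()
    duplex = validate_duplex(construct.guide, construct.passenger)
    mass = average_mass(construct, table)
    return {
        "name": construct.name,
        "form": construct.form,
        "guide_length": len(construct.guide),
        "passenger_length": len(construct.passenger),
        "guide_overhang": duplex.guide_overhang,
        "modification_fractions": modification_fractions(construct),
        "average_mass_g_per_mol": mass,
        "doses_ug": {str(d): dose_mass(d, construct, table) for d in doses_nmol},
    }
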