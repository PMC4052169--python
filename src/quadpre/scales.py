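"""Physicochemical scales and amino-acid grouping tables.

Four per-residue scales drive the sequence feature block:

* ``PI`` — isoelectric points of the free amino acids (Lehninger values).
* ``FH`` — Fauchere & Pliska (1983) octanol/water side-chain
  hydrophobicity (pi values).
* ``EH`` — Eisenberg et al. (1984) normalized consensus hydrophobicity.
* ``HP`` — Kyte & Doolittle (1982) hydropathy index.

Four groupings aggregate residues into chemically similar sets: the five
R groups (side-chain chemistry), five electronic groups (electron
donor/acceptor character), three hydrophobicity groups, and five
exchange groups (mutation-tolerant substitution sets).  Every grouping
partitions the 20 standard residues.

All tables are defaults and can be overridden from a YAML config via
:func:`load_scales`, so alternative literature values can be dropped in
without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import yaml

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

#: Isoelectric point of the free amino acid.
PI: Dict[str, float] = {
    "A": 6.01, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.48,
    "S": 5.68, "T": 5.87, "W": 5.89, "Y": 5.66, "V": 5.97,
}

#: Fauchere-Pliska side-chain hydrophobicity (octanol scale).
FH: Dict[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: Eisenberg normalized consensus hydrophobicity.
EH: Dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: Kyte-Doolittle hydropathy.
HP: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Groupings.  Each is an ordered list of (name, members); members jointly
# partition the 20 standard residues.
R_GROUPS: List[Tuple[str, str]] = [
    ("nonpolar_aliphatic", "AVLIMG"),
    ("polar_uncharged", "SPTCNQ"),
    ("positively_charged", "KHR"),
    ("negatively_charged", "DE"),
    ("aromatic", "FYW"),
]

# The classical electronic grouping names only 19 residues; cysteine is
# folded into the neutral set so the five groups partition all 20 and
# the composition percentages sum to one.
ELECTRONIC_GROUPS: List[Tuple[str, str]] = [
    ("electron_donor", "DEPA"),
    ("weak_electron_donor", "LIV"),
    ("electron_acceptor", "KNR"),
    ("weak_electron_acceptor", "FYMTQ"),
    ("neutral", "GHWSC"),
]

HYDROPHOBICITY_GROUPS: List[Tuple[str, str]] = [
    ("hydrophobic", "CFILMVW"),
    ("neutral", "AGHPSTY"),
    ("polar", "DEKNQR"),
]

# Exchange (substitution-tolerant) groups.  The classic six-set scheme
# keeps the aromatics FYW separate; here they are folded into the large
# hydrophobic set so the grouping has five sets and the four groupings
# together give exactly 18 group-count features.
EXCHANGE_GROUPS: List[Tuple[str, str]] = [
    ("sulfhydryl", "C"),
    ("small", "AGPST"),
    ("acid_amide", "DENQ"),
    ("basic", "HKR"),
    ("hydrophobic_aromatic", "ILMVFYW"),
]


def _check_partition(groups: List[Tuple[str, str]], label: str) -> None:
    joined = "".join(members for _, members in groups)
    if sorted(joined) != sorted(STANDARD_AAS):
        raise ValueError(f"{label} grouping does not partition the 20 standard residues")


def _check_scale(scale: Dict[str, float], label: str) -> None:
    if set(scale) != set(STANDARD_AAS):
        raise ValueError(f"{label} scale must define all 20 standard residues exactly")


@dataclass(frozen=True)
class PhysicoScales:
    """Bundle of the residue scales and grouping tables used by the encoder."""

    pi: Dict[str, float] = field(default_factory=lambda: dict(PI))
    fh: Dict[str, float] = field(default_factory=lambda: dict(FH))
    eh: Dict[str, float] = field(default_factory=lambda: dict(EH))
    hp: Dict[str, float] = field(default_factory=lambda: dict(HP))
    r_groups: List[Tuple[str, str]] = field(default_factory=lambda: list(R_GROUPS))
    electronic_groups: List[Tuple[str, str]] = field(
        default_factory=lambda: list(ELECTRONIC_GROUPS))
    hydrophobicity_groups: List[Tuple[str, str]] = field(
        default_factory=lambda: list(HYDROPHOBICITY_GROUPS))
    exchange_groups: List[Tuple[str, str]] = field(
        default_factory=lambda: list(EXCHANGE_GROUPS))

    def __post_init__(self) -> None:
        for scale, label in ((self.pi, "pI"), (self.fh, "FH"),
                             (self.eh, "EH"), (self.hp, "HP")):
            _check_scale(scale, label)
        for groups, label in ((self.r_groups, "R"),
                              (self.electronic_groups, "electronic"),
                              (self.hydrophobicity_groups, "hydrophobicity"),
                              (self.exchange_groups, "exchange")):
            _check_partition(groups, label)

    def scale(self, name: str) -> Dict[str, float]:
        try:
            return {"FH": self.fh, "EH": self.eh, "HP": self.hp, "PI": self.pi}[name]
        except KeyError:
            raise KeyError(f"unknown scale {name!r}; expected FH, EH, HP or PI") from None

    def all_groupings(self) -> List[Tuple[str, List[Tuple[str, str]]]]:
        """Groupings in the fixed order used by the 18 group-count features."""
        return [
            ("R", self.r_groups),
            ("electronic", self.electronic_groups),
            ("hydrophobicity", self.hydrophobicity_groups),
            ("exchange", self.exchange_groups),
        ]


DEFAULT_SCALES = PhysicoScales()


def load_scales(path: str | None = None) -> PhysicoScales:
    """Load scales from a YAML config, falling back to defaults per key.

    Recognised keys: ``pi``, ``fh``, ``eh``, ``hp`` (residue -> value
    maps) and ``r_groups``, ``electronic_groups``,
    ``hydrophobicity_groups``, ``exchange_groups`` (lists of
    ``[name, members]`` pairs).
    """
    if path is None:
        return DEFAULT_SCALES
    with open(path) as fh_:
        cfg = yaml.safe_load(fh_) or {}
    kwargs = {}
    for key in ("pi", "fh", "eh", "hp"):
        if key in cfg:
            kwargs[key] = {str(k).upper(): float(v) for k, v in cfg[key].items()}
    for key in ("r_groups", "electronic_groups",
                "hydrophobicity_groups", "exchange_groups"):
        if key in cfg:
            kwargs[key] = [(str(name), str(members).upper()) for name, members in cfg[key]]
    return PhysicoScales(**kwargs)
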