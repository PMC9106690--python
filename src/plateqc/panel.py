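"""Compound catalogue for a 408-metabolite targeted kit panel.

The kit measures 11 metabolite classes split between two acquisition modes:
amino acids and biogenic amines by liquid chromatography (LC, integrated peak
areas) and all lipid classes plus hexose by flow-injection analysis (FIA, peak
intensities).  Every compound is paired with an isotopically labelled internal
standard used for normalization.

The built-in ``p400`` panel reproduces the published class composition exactly
(42 LC + 366 FIA = 408 compounds).  The full list of individual lipid species
names is vendor-proprietary, so lipid compounds carry systematic placeholder
names (class prefix + index); amino acids and biogenic amines use their common
abbreviations.  Real exports are matched by name through a user-supplied panel
CSV with columns ``name, class, measurement_type, internal_standard_id``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import PanelFormatError

LC = "LC"
FIA = "FIA"

#: (class name, measurement type, expected compound count, IS id, name prefix)
_CLASS_SPECS: tuple[tuple[str, str, int, str, str], ...] = (
    ("amino acids", LC, 21, "IS_AA", "AA"),
    ("biogenic amines", LC, 21, "IS_BA", "BA"),
    ("hexose", FIA, 1, "IS_HEX", "Hex"),
    ("acylcarnitines", FIA, 55, "IS_AC", "AC"),
    ("cholesteryl esters", FIA, 14, "IS_CE", "CE"),
    ("diglycerides", FIA, 18, "IS_DG", "DG"),
    ("triglycerides", FIA, 42, "IS_TG", "TG"),
    ("phosphatidylcholines", FIA, 172, "IS_PC", "PC"),
    ("lysophosphatidylcholines", FIA, 24, "IS_LPC", "LPC"),
    ("sphingomyelins", FIA, 31, "IS_SM", "SM"),
    ("ceramides", FIA, 9, "IS_CER", "Cer"),
)

CLASS_NAMES: tuple[str, ...] = tuple(s[0] for s in _CLASS_SPECS)
_CLASS_TYPE: dict[str, str] = {s[0]: s[1] for s in _CLASS_SPECS}

_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cit Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser "
    "Thr Trp Tyr Val"
).split()

_BIOGENIC_AMINES = (
    "Ac-Orn ADMA alpha-AAA Carnosine Creatine Creatinine DOPA Dopamine "
    "Histamine Kynurenine Met-SO Nitro-Tyr PEA Putrescine Sarcosine SDMA "
    "Serotonin Spermidine Spermine t4-OH-Pro Taurine"
).split()


@dataclass(frozen=True)
class CompoundClass:
    """One of the kit's 11 metabolite classes."""

    name: str
    measurement_type: str
    expected_count: int

    def __post_init__(self) -> None:
        if self.measurement_type not in (LC, FIA):
            raise PanelFormatError(
                f"unknown measurement type {self.measurement_type!r} "
                f"for class {self.name!r}"
            )
        if self.expected_count < 0:
            raise PanelFormatError(f"negative count for class {self.name!r}")


@dataclass(frozen=True)
class PanelCompound:
    """A single analyte: name, class membership and its internal standard."""

    name: str
    compound_class: CompoundClass
    internal_standard_id: str

    @property
    def measurement_type(self) -> str:
        return self.compound_class.measurement_type


@dataclass
class Panel:
    """Ordered compound catalogue plus class metadata."""

    compounds: list[PanelCompound]
    classes: list[CompoundClass]
    _by_name: dict[str, PanelCompound] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {c.name: c for c in self.compounds}
        if len(self._by_name) != len(self.compounds):
            seen: set[str] = set()
            for c in self.compounds:
                if c.name in seen:
                    raise PanelFormatError(f"duplicate compound name {c.name!r}")
                seen.add(c.name)
        if not self.compounds:
            raise PanelFormatError("empty panel rejected")

    def __len__(self) -> int:
        return len(self.compounds)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    @property
    def istd_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.compounds:
            seen.setdefault(c.internal_standard_id)
        return list(seen)

    def compound(self, name: str) -> PanelCompound:
        return self._by_name[name]

    def istd_of(self, name: str) -> str:
        return self._by_name[name].internal_standard_id

    def measurement_type_of(self, name: str) -> str:
        return self._by_name[name].measurement_type

    def names_of_type(self, measurement_type: str) -> list[str]:
        return [
            c.name
            for c in self.compounds
            if c.measurement_type == measurement_type
        ]

    def names_of_class(self, class_name: str) -> list[str]:
        return [
            c.name
            for c in self.compounds
            if c.compound_class.name == class_name
        ]

    def class_of(self, name: str) -> str:
        return self._by_name[name].compound_class.name


def _builtin_p400() -> Panel:
    classes = [CompoundClass(n, t, c) for n, t, c, _, _ in _CLASS_SPECS]
    compounds: list[PanelCompound] = []
    for cls, (name, _t, count, istd, prefix) in zip(classes, _CLASS_SPECS):
        if name == "amino acids":
            names = list(_AMINO_ACIDS)
        elif name == "biogenic amines":
            names = list(_BIOGENIC_AMINES)
        elif name == "hexose":
            names = ["Hexoses"]
        else:
            names = [f"{prefix} {i:03d}" for i in range(1, count + 1)]
        if len(names) != count:
            raise AssertionError(f"class {name} name list length mismatch")
        compounds.extend(PanelCompound(n, cls, istd) for n in names)
    return Panel(compounds, classes)


def load_panel(source: str | Path) -> Panel:
    """Load the built-in ``"p400"`` panel or a panel definition CSV.

    The CSV needs a header row with columns ``name``, ``class``,
    ``measurement_type`` and ``internal_standard_id``; class labels must be
    one of the 11 known classes and the measurement type must match the
    class's acquisition mode.
    """
    if source == "p400":
        return _builtin_p400()
    path = Path(source)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "class", "measurement_type", "internal_standard_id"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or ()))
            raise PanelFormatError(f"panel CSV missing columns: {missing}")
        rows = list(reader)
    if not rows:
        raise PanelFormatError("empty panel rejected")

    counts: dict[str, int] = {}
    for row in rows:
        cls = row["class"]
        if cls not in _CLASS_TYPE:
            raise PanelFormatError(f"unknown class label {cls!r}")
        if row["measurement_type"] != _CLASS_TYPE[cls]:
            raise PanelFormatError(
                f"class {cls!r} is measured by {_CLASS_TYPE[cls]}, "
                f"got {row['measurement_type']!r} for {row['name']!r}"
            )
        counts[cls] = counts.get(cls, 0) + 1

    classes = {
        cls: CompoundClass(cls, _CLASS_TYPE[cls], n) for cls, n in counts.items()
    }
    compounds = [
        PanelCompound(row["name"], classes[row["class"]],
                      row["internal_standard_id"])
        for row in rows
    ]
    return Panel(compounds, [classes[c] for c in CLASS_NAMES if c in classes])


def make_panel(class_sizes: dict[str, int]) -> Panel:
    """Build a reduced panel with placeholder names, for small studies/tests.

    ``class_sizes`` maps known class labels to compound counts; measurement
    types and internal standards follow the class.
    """
    prefix = {s[0]: s[4] for s in _CLASS_SPECS}
    istd = {s[0]: s[3] for s in _CLASS_SPECS}
    classes, compounds = [], []
    for name, count in class_sizes.items():
        if name not in _CLASS_TYPE:
            raise PanelFormatError(f"unknown class label {name!r}")
        cls = CompoundClass(name, _CLASS_TYPE[name], count)
        classes.append(cls)
        compounds.extend(
            PanelCompound(f"{prefix[name]} {i:03d}", cls, istd[name])
            for i in range(1, count + 1))
    return Panel(compounds, classes)


def class_counts(panel: Panel, measurement_type: str | None = None) -> dict[str, int]:
    """Compound count per class, optionally restricted to LC or FIA."""
    out: dict[str, int] = {}
    for c in panel.compounds:
        if measurement_type is not None and c.measurement_type != measurement_type:
            continue
        out[c.compound_class.name] = out.get(c.compound_class.name, 0) + 1
    return out
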