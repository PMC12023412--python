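"""Per-amino-acid numeric scales and scale-delta computation.

The mass-balance correction approximates the unfolded-state free-energy
difference of a single-point mutation by per-residue terms.  Its
two-parameter variant replaces fitted residue coefficients with a fixed
experimental scale: the mean buried surface area of Rose et al., which
tracks the solvation cost of transferring a residue from water into the
protein core.  The Kyte-Doolittle hydropathy scale is carried alongside
for coefficient-correlation analysis.

Scales are total, immutable mappings over the 20 canonical amino acids.
A module-level registry maps names to :class:`Scale`; custom scales can
be registered programmatically or loaded from a two-column TSV.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Iterable, Mapping

from .errors import FormatError, InvalidResidueError, NotFoundError

#: The 20 canonical amino acids, fixed alphabetical one-letter order.
#: This order also indexes occurrence vectors and coefficient vectors.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

_AA_SET = frozenset(AMINO_ACIDS)

#: Position of each residue in AMINO_ACIDS.
AA_INDEX: Mapping[str, int] = MappingProxyType(
    {aa: i for i, aa in enumerate(AMINO_ACIDS)}
)


def validate_residue(symbol: str) -> str:
    """Normalize a one-letter residue symbol to uppercase and validate it.

    Raises
    ------
    InvalidResidueError
        If the symbol is not one of the 20 canonical amino acids.
        Ambiguity codes (B, Z, X) and rare residues (U, O) are rejected,
        not imputed: the mutation encoding is defined only over the 20
        canonical residues.
    """
    if not isinstance(symbol, str):
        raise InvalidResidueError(f"residue symbol must be a string, got {symbol!r}")
    code = symbol.strip().upper()
    if code not in _AA_SET:
        raise InvalidResidueError(
            f"{symbol!r} is not a canonical amino acid (expected one of "
            f"{''.join(AMINO_ACIDS)})"
        )
    return code


class Scale:
    """A named, immutable per-amino-acid numeric scale.

    Parameters
    ----------
    name : str
        Registry identifier.
    values : mapping
        One finite float per canonical amino acid (exactly 20 entries;
        keys are normalized to uppercase).
    """

    __slots__ = ("name", "_values")

    def __init__(self, name: str, values: Mapping[str, float]):
        normalized: dict[str, float] = {}
        for aa, v in values.items():
            code = validate_residue(aa)
            normalized[code] = float(v)
        missing = _AA_SET - normalized.keys()
        if missing:
            raise FormatError(
                f"scale {name!r} is missing residues: {''.join(sorted(missing))}"
            )
        for aa, v in normalized.items():
            if v != v or v in (float("inf"), float("-inf")):
                raise FormatError(f"scale {name!r} has non-finite value for {aa}")
        self.name = name
        self._values = MappingProxyType(dict(sorted(normalized.items())))

    def __getitem__(self, residue: str) -> float:
        return self._values[validate_residue(residue)]

    def __iter__(self):
        return iter(AMINO_ACIDS)

    def __len__(self) -> int:
        return 20

    def __repr__(self) -> str:
        return f"Scale({self.name!r})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Scale):
            return NotImplemented
        return self.name == other.name and dict(self._values) == dict(other._values)

    def as_dict(self) -> dict[str, float]:
        """Return a plain dict copy keyed by residue letter."""
        return dict(self._values)

    def as_vector(self) -> list[float]:
        """Values in fixed alphabetical residue order (A, C, D, ..., Y)."""
        return [self._values[aa] for aa in AMINO_ACIDS]


# Kyte & Doolittle (1982) J Mol Biol 157:105-132, Table 1 — hydropathy
# index, dimensionless.  Transcribed from the original table.
KYTE_DOOLITTLE = Scale(
    "kyte_doolittle",
    {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
        "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
        "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
        "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
    },
)

# Rose, Geselowitz, Lesser, Lee & Zehfus (1985) Science 229:834-838 —
# mean area buried on transfer from the standard state to the folded
# protein, in A^2.  Transcribed from the original table (also AAindex
# entry ROSG850101).
ROSE = Scale(
    "rose",
    {
        "A": 86.6, "C": 132.3, "D": 97.8, "E": 113.9, "F": 194.1,
        "G": 62.9, "H": 155.8, "I": 158.0, "K": 115.5, "L": 164.1,
        "M": 172.9, "N": 103.3, "P": 92.9, "Q": 119.2, "R": 162.2,
        "S": 85.6, "T": 106.5, "V": 141.0, "W": 224.6, "Y": 177.7,
    },
)

_REGISTRY: dict[str, Scale] = {
    KYTE_DOOLITTLE.name: KYTE_DOOLITTLE,
    ROSE.name: ROSE,
}


def registered_scales() -> list[str]:
    """Names of all currently registered scales."""
    return sorted(_REGISTRY)


def register_scale(scale: Scale, overwrite: bool = False) -> None:
    """Add a scale to the registry.

    Raises :class:`FormatError` if the name is taken and ``overwrite``
    is false.
    """
    if scale.name in _REGISTRY and not overwrite:
        raise FormatError(f"scale {scale.name!r} already registered")
    _REGISTRY[scale.name] = scale


def get_scale(name: str) -> Scale:
    """Look up a registered scale by name.

    Raises
    ------
    NotFoundError
        Unknown name; the message lists the registered scales.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise NotFoundError(
            f"unknown scale {name!r}; registered scales: {', '.join(registered_scales())}"
        ) from None


def scale_delta(wt: str, mut: str, scale: Scale) -> float:
    """Difference scale[mut] - scale[wt] for a single-point mutation.

    Antisymmetric by construction: swapping the residues negates the
    result, and identity mutations give exactly 0.0.
    """
    return scale[mut] - scale[wt]


def read_scale_tsv(path, name: str | None = None) -> Scale:
    """Load a scale from a two-column TSV (residue <TAB> value).

    A header line is permitted and skipped if its second field is not
    numeric.  The file must cover all 20 canonical residues exactly once.
    """
    import pathlib

    p = pathlib.Path(path)
    values: dict[str, float] = {}
    lines = p.read_text(encoding="utf-8").splitlines()
    for i, line in enumerate(lines):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{p}: line {i + 1}: expected 2 tab-separated fields")
        residue, raw = parts[0].strip(), parts[1].strip()
        try:
            value = float(raw)
        except ValueError:
            if i == 0:  # header row
                continue
            raise FormatError(f"{p}: line {i + 1}: non-numeric value {raw!r}") from None
        code = validate_residue(residue)
        if code in values:
            raise FormatError(f"{p}: duplicate residue {code}")
        values[code] = value
    return Scale(name or p.stem, values)


def write_scale_tsv(scale: Scale, path) -> None:
    """Write a scale as a two-column TSV with a ``residue\\tvalue`` header."""
    import pathlib

    lines = ["residue\tvalue"]
    lines += [f"{aa}\t{scale[aa]!r}" for aa in AMINO_ACIDS]
    pathlib.Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_scales_config(paths: Iterable) -> None:
    """Register custom scales from TSV files (filename stem = scale name)."""
    for path in paths:
        register_scale(read_scale_tsv(path), overwrite=True)
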