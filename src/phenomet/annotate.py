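"""Molecular formulas, monoisotopic masses, adduct m/z and ppm annotation.

Annotates aligned LC-MS features (ids of the form ``"<rt>_<mz>"``) against
a compound database by exact mass only: each (feature, compound, adduct)
triple within the ppm tolerance is reported, ranked by |ppm|.

Adduct m/z values are computed without electron-mass correction by
default; pass ``electron_correction=True`` to subtract m_e per positive
charge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "AdductRule",
    "parse_formula",
    "formula_to_text",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate_features",
    "read_feature_table",
    "write_feature_table",
    "read_compound_db",
    "write_annotations",
    "DEFAULT_ADDUCTS",
]

# monoisotopic atomic masses (Da)
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "Na": 22.9897693,
    "S": 31.97207117,
    "P": 30.97376200,
    "K": 38.96370649,
    "Cl": 34.96885268,
    "F": 18.99840316,
    "Br": 78.9183376,
    "I": 126.9044719,
    "Si": 27.97692653,
}

ELECTRON_MASS = 0.000548579909  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_MARKUP = re.compile(r"[\s_^*]")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string into element counts.

    Subscript markup (``C_22_H_35_NO_5_``) and whitespace are stripped
    first.  Unknown element symbols raise with the symbol named.
    """
    clean = _MARKUP.sub("", text)
    if not clean:
        raise ValueError(f"empty formula {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(clean):
        m = _FORMULA_TOKEN.match(clean, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"cannot parse formula {text!r} at {clean[pos:]!r}")
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


def formula_to_text(counts: dict[str, int]) -> str:
    """Canonical Hill order: C, H, then remaining elements alphabetically."""
    parts = []
    for sym in ["C", "H"] + sorted(set(counts) - {"C", "H"}):
        n = counts.get(sym, 0)
        if n > 0:
            parts.append(sym + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Neutral monoisotopic mass in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula:
        raise ValueError("formula must contain at least one element")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())


_ADDUCT_NAME = re.compile(r"^\[M((?:\s*[+−–-]\s*[A-Za-z0-9]+)*)\]\+$")
_ADDUCT_PART = re.compile(r"([+−–-])\s*([A-Za-z0-9]+)")


@dataclass(frozen=True)
class AdductRule:
    """Singly charged adduct: name and neutral mass delta in Da."""

    name: str
    mass_delta: float
    charge: int = 1

    @classmethod
    def from_name(cls, name: str) -> "AdductRule":
        """Parse names like ``[M+H]+``, ``[M+Na]+``, ``[M+H-H2O-CH2O]+``.

        The mass delta is the sum of gained minus lost fragment
        monoisotopic masses.
        """
        clean = _MARKUP.sub("", name)
        m = _ADDUCT_NAME.match(clean)
        if m is None:
            raise ValueError(f"cannot parse adduct name {name!r}")
        delta = 0.0
        for sign, frag in _ADDUCT_PART.findall(m.group(1)):
            mass = monoisotopic_mass(parse_formula(frag))
            delta += mass if sign == "+" else -mass
        return cls(name=name, mass_delta=delta)


DEFAULT_ADDUCTS = [
    AdductRule.from_name("[M+H]+"),
    AdductRule.from_name("[M+Na]+"),
    AdductRule.from_name("[M+K]+"),
    AdductRule.from_name("[M+H-H2O]+"),
    AdductRule.from_name("[M+H-H2O-CH2O]+"),
]


def adduct_mz(neutral_mass: float, rule: AdductRule,
              electron_correction: bool = False) -> float:
    """Theoretical m/z of a singly charged adduct ion."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    mz = neutral_mass + rule.mass_delta
    if electron_correction:
        mz -= ELECTRON_MASS * rule.charge
    return mz


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass accuracy in parts per million."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return (observed - theoretical) / theoretical * 1e6


def annotate_features(
    table: pd.DataFrame,
    db: pd.DataFrame,
    rules: list[AdductRule] | None = None,
    tol_ppm: float = 10.0,
    electron_correction: bool = False,
) -> pd.DataFrame:
    """All (feature, compound, adduct) matches within ``tol_ppm``.

    ``table`` is a feature table whose index holds ``"rt_mz"`` ids (see
    :func:`read_feature_table`); ``db`` needs columns ``name`` and
    ``formula``.  Output columns: feature, compound, adduct,
    theoretical_mz, ppm — sorted by |ppm| then feature id.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if rules is None:
        rules = DEFAULT_ADDUCTS
    if len(db) == 0:
        logger.warning("empty compound database: no annotations produced")
        return pd.DataFrame(
            columns=["feature", "compound", "adduct", "theoretical_mz", "ppm"]
        )
    masses = [
        (row["name"], monoisotopic_mass(parse_formula(row["formula"])))
        for _, row in db.iterrows()
    ]
    records = []
    for fid in table.index:
        mz_obs = float(str(fid).rsplit("_", 1)[1])
        for name, M in masses:
            for rule in rules:
                theo = adduct_mz(M, rule, electron_correction)
                ppm = ppm_error(mz_obs, theo)
                if abs(ppm) <= tol_ppm:
                    records.append(
                        {"feature": fid, "compound": name, "adduct": rule.name,
                         "theoretical_mz": theo, "ppm": ppm}
                    )
    out = pd.DataFrame(records,
                       columns=["feature", "compound", "adduct", "theoretical_mz", "ppm"])
    return out.sort_values(["ppm", "feature"], key=lambda c: c.abs() if c.name == "ppm" else c,
                           ignore_index=True)


# ---------------------------------------------------------------------------
# CSV dialects

def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Aligned feature CSV: first column ``"rt_mz"`` id, then sample columns."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    for fid in df.index:
        parts = fid.rsplit("_", 1)
        if len(parts) != 2:
            raise ValueError(f"feature id {fid!r} is not of the form 'rt_mz'")
        float(parts[0]), float(parts[1])  # raises on malformed ids
    if df.index.duplicated().any():
        raise ValueError("duplicate feature ids in table")
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="feature")


def read_compound_db(path: str | Path) -> pd.DataFrame:
    db = pd.read_csv(path)
    required = {"name", "formula"}
    if not required <= set(db.columns):
        raise ValueError(f"compound DB needs columns {sorted(required)}")
    return db


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    """Annotation CSV with ppm printed at 1 decimal place."""
    out = annotations.copy()
    out["ppm"] = out["ppm"].map(lambda v: f"{v:.1f}")
    out.to_csv(path, index=False)
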