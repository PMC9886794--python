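"""Rule-based amino-acid substitution classification.

A substitution is compared across four R-group properties — charge,
polarity, hydropathy, and size class — and labeled

* ``C``  (conservative): zero property differences;
* ``NC`` (non-conservative): at least one difference;
* ``R``  (radical): two or more differences *including* a size change
  (size is singled out because of its potential for steric clashes).

The property table ships as an editable TSV (``data/aa_properties.tsv``).
Its conventions: charge positive K/R/H, negative D/E; polarity polar for
S/T/C/Y/N/Q/D/E/K/R/H; hydropathy by the sign of the Kyte-Doolittle index
(> 0 hydrophobic, < -1 hydrophilic, [-1, 0] neutral); size class by
residue volume bins (tiny < 95 A^3, small 95-125, medium 125-160,
large >= 160). Alternative conventions can be tested by swapping the file.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

PROPERTY_NAMES = ("charge", "polarity", "hydropathy", "size_class")

#: Residue codes the classifier refuses (ambiguity/selenocysteine/stop).
NON_CANONICAL = frozenset("BZXJUO*")


class ResidueError(ValueError):
    """Raised for a non-canonical residue code."""


@dataclass(frozen=True)
class AAProperty:
    residue: str
    charge: str
    polarity: str
    hydropathy: str
    size_class: str


@dataclass(frozen=True)
class AAChange:
    """One amino-acid substitution with its property-difference audit."""

    ref_aa: str
    alt_aa: str
    position: int | None
    diff_vector: tuple[bool, bool, bool, bool]  # per PROPERTY_NAMES
    n_diffs: int
    label: str  # "C" | "NC" | "R"


def load_property_table(path: str | Path | None = None
                        ) -> dict[str, AAProperty]:
    """Load the residue property table (packaged TSV by default)."""
    if path is None:
        source = resources.files("mitolav.data") / "aa_properties.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, AAProperty] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        table[row["residue"]] = AAProperty(
            residue=row["residue"], charge=row["charge"],
            polarity=row["polarity"], hydropathy=row["hydropathy"],
            size_class=row["size_class"],
        )
    if len(table) != 20:
        raise ValueError(f"property table must cover exactly 20 residues, "
                         f"got {len(table)}")
    return table


_DEFAULT_TABLE: dict[str, AAProperty] | None = None


def _table() -> dict[str, AAProperty]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_property_table()
    return _DEFAULT_TABLE


def classify(ref_aa: str, alt_aa: str, position: int | None = None,
             table: dict[str, AAProperty] | None = None) -> AAChange:
    """Classify a substitution as C, NC, or R.

    The rule is literal: R requires >= 2 property differences *and* one of
    them to be size; >= 2 differences without a size change stays NC.
    """
    if table is None:
        table = _table()
    for aa in (ref_aa, alt_aa):
        if aa not in table:
            raise ResidueError(
                f"non-canonical residue {aa!r}: classification is defined "
                f"only for the 20 canonical amino acids"
            )
    p_ref, p_alt = table[ref_aa], table[alt_aa]
    diffs = tuple(getattr(p_ref, name) != getattr(p_alt, name)
                  for name in PROPERTY_NAMES)
    n = sum(diffs)
    size_changed = diffs[PROPERTY_NAMES.index("size_class")]
    if n == 0:
        label = "C"
    elif n >= 2 and size_changed:
        label = "R"
    else:
        label = "NC"
    return AAChange(ref_aa=ref_aa, alt_aa=alt_aa, position=position,
                    diff_vector=diffs, n_diffs=n, label=label)


_HGVS_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


def parse_hgvs_p(text: str) -> tuple[str, int, str]:
    """Parse a one-letter HGVS-style protein change like ``p.K123E``."""
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse amino-acid change {text!r}")
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


def classify_table(records: Iterable, table: dict[str, AAProperty] | None
                   = None) -> list:
    """Attach an ``AAChange`` to every nonsynonymous record.

    Non-nonsynonymous records pass through untouched (stop gains have no
    alt residue and are not classified). A nonsynonymous record without an
    ``aa_change`` annotation gets ``aa_label = None`` (missing, logged).
    """
    import logging
    log = logging.getLogger(__name__)
    out = []
    for rec in records:
        if rec.consequence_class == "nonsynonymous":
            raw = rec.annotations.get("aa_change")
            if raw:
                ref_aa, pos, alt_aa = parse_hgvs_p(str(raw))
                change = classify(ref_aa, alt_aa, pos, table)
                rec.annotations["aa_label"] = change.label
                rec.annotations["aa_n_diffs"] = change.n_diffs
            else:
                rec.annotations["aa_label"] = None
                log.info("nonsynonymous variant %s lacks aa_change; "
                         "label set to missing", rec.key)
        out.append(rec)
    return out
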