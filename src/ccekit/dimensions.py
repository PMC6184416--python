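"""Classification axes for expenditure reporting.

Maps ICD-10 codes to their standard chapters and to broad Global Burden of
Disease (GBD) cause groups, and ages to the three reporting bands
(0-14, 15-64, >=65).  The GBD mapping ships as an editable CSV
(``ccekit/data/gbd_map.csv``) following the classical convention:

* group I   - communicable, maternal, perinatal and nutritional conditions
* group II  - non-communicable diseases
* group III - injuries (both external-cause V-Y and nature-of-injury S-T codes)
* other     - symptoms/ill-defined (R00-R99), health-service contact (Z) and
  provisional (U) codes, plus anything a custom table leaves unmapped

The table is data, not code, so analysts can audit or override it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import ValidationError

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")

GBD_GROUPS = (
    "group_I_infectious_maternal_perinatal",
    "group_II_ncd",
    "group_III_injury",
    "other_unclassified",
)

AGE_BANDS = ("0-14", "15-64", ">=65")

# Standard ICD-10 chapters: (start, end, label); ends inclusive.
_CHAPTERS = [
    ("A00", "B99", "Certain infectious and parasitic diseases"),
    ("C00", "D48", "Neoplasms"),
    ("D50", "D89", "Diseases of the blood and blood-forming organs"),
    ("E00", "E90", "Endocrine, nutritional and metabolic diseases"),
    ("F00", "F99", "Mental and behavioural disorders"),
    ("G00", "G99", "Diseases of the nervous system"),
    ("H00", "H59", "Diseases of the eye and adnexa"),
    ("H60", "H95", "Diseases of the ear and mastoid process"),
    ("I00", "I99", "Diseases of the circulatory system"),
    ("J00", "J99", "Diseases of the respiratory system"),
    ("K00", "K93", "Diseases of the digestive system"),
    ("L00", "L99", "Diseases of the skin and subcutaneous tissue"),
    ("M00", "M99", "Diseases of the musculoskeletal system and connective tissue"),
    ("N00", "N99", "Diseases of the genitourinary system"),
    ("O00", "O99", "Pregnancy, childbirth and the puerperium"),
    ("P00", "P96", "Certain conditions originating in the perinatal period"),
    ("Q00", "Q99", "Congenital malformations, deformations and chromosomal abnormalities"),
    ("R00", "R99", "Symptoms, signs and abnormal clinical and laboratory findings"),
    ("S00", "T98", "Injury, poisoning and certain other consequences of external causes"),
    ("U00", "U99", "Codes for special purposes"),
    ("V01", "Y98", "External causes of morbidity and mortality"),
    ("Z00", "Z99", "Factors influencing health status and contact with health services"),
]

GENITOURINARY_CHAPTER = "Diseases of the genitourinary system"


def _code_key(code: str) -> tuple[str, int]:
    """Sortable key (letter, 2-digit number) of an ICD-10 code, ignoring
    any sub-classification after the decimal point."""
    return code[0], int(code[1:3])


def validate_icd10(code: str) -> str:
    """Return ``code`` if it matches the ICD-10 pattern, else raise."""
    if not isinstance(code, str) or not ICD10_PATTERN.match(code):
        raise ValidationError(f"malformed ICD-10 code: {code!r}")
    return code


def icd10_chapter(code: str) -> str:
    """Standard ICD-10 chapter label for a code (e.g. N18 -> genitourinary)."""
    validate_icd10(code)
    key = _code_key(code)
    # Codes in the gaps between listed ends (unassigned in ICD-10, e.g. D49,
    # D90-D99) fall to the chapter whose start precedes them, keeping the
    # mapping total over all syntactically valid codes.
    label = _CHAPTERS[0][2]
    for start, _end, chapter_label in _CHAPTERS:
        if _code_key(start) <= key:
            label = chapter_label
        else:
            break
    return label


def is_genitourinary(code: str) -> bool:
    return icd10_chapter(code) == GENITOURINARY_CHAPTER


@dataclass(frozen=True)
class MappingTable:
    """Ordered ICD-10 range -> GBD-group rules.

    Ranges must be disjoint; codes outside every range fall through to
    ``other_unclassified`` (never an exception).
    """

    rules: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        keyed = []
        for start, end, group in self.rules:
            validate_icd10(start)
            validate_icd10(end)
            if group not in GBD_GROUPS:
                raise ValidationError(f"unknown GBD group label: {group!r}")
            lo, hi = _code_key(start), _code_key(end)
            if lo > hi:
                raise ValidationError(f"inverted range {start}-{end}")
            keyed.append((lo, hi, group))
        keyed.sort()
        for (_, hi_a, _), (lo_b, _, _) in zip(keyed, keyed[1:]):
            if lo_b <= hi_a:
                raise ValidationError(
                    f"overlapping GBD ranges near {lo_b[0]}{lo_b[1]:02d}"
                )
        object.__setattr__(self, "_keyed", tuple(keyed))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MappingTable":
        required = {"range_start", "range_end", "group"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"mapping table missing columns: {sorted(missing)}")
        return cls(
            tuple(
                (str(r.range_start), str(r.range_end), str(r.group))
                for r in frame.itertuples()
            )
        )

    @classmethod
    def from_csv(cls, path) -> "MappingTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default(cls) -> "MappingTable":
        with resources.files("ccekit.data").joinpath("gbd_map.csv").open() as fh:
            return cls.from_frame(pd.read_csv(fh))

    def lookup(self, code: str) -> str:
        key = _code_key(validate_icd10(code))
        for lo, hi, group in self._keyed:  # type: ignore[attr-defined]
            if lo <= key <= hi:
                return group
        return "other_unclassified"


def gbd_group(code: str, table: MappingTable | None = None) -> str:
    """GBD broad cause group of an ICD-10 code under ``table`` (default
    bundled mapping)."""
    if table is None:
        table = MappingTable.default()
    return table.lookup(code)


def age_band(age: int) -> str:
    """Reporting age band: 0-14, 15-64 or >=65 (65-and-over inclusive)."""
    if age < 0 or age != int(age):
        raise ValidationError(f"invalid age: {age!r}")
    if age <= 14:
        return "0-14"
    if age <= 64:
        return "15-64"
    return ">=65"
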