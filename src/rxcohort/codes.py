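"""ATC code vocabulary for the antidepressant dispensing analysis.

The WHO Anatomical Therapeutic Chemical (ATC) classification is hierarchical:
one letter for the anatomical group, two digits, then one or two letters for
the therapeutic/chemical subgroup, then two digits for the substance
(e.g. ``N06AB03`` = fluoxetine). Antidepressants live under ``N06A``; the
analysis covers tricyclics (N06AA), SSRIs (N06AB) and "other" antidepressants
(N06AX), while MAOIs (N06AF, N06AG) are out of scope because they are not
plausible first-line drugs.
"""

from __future__ import annotations

import re

ATC_PATTERN = re.compile(r"^[A-Z][0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?$")

#: ATC prefixes counted as antidepressants for cohort entry.
ANTIDEPRESSANT_PREFIXES = ("N06AA", "N06AB", "N06AX")
#: MAOI prefixes, deliberately not counted.
MAOI_PREFIXES = ("N06AF", "N06AG")

#: Desmopressin, first-line bed-wetting treatment (exclusion marker).
DESMOPRESSIN = "H01BA02"
#: Pain-related medication: anti-inflammatories, analgesics, gabapentin, pregabalin.
PAIN_PREFIXES = ("M01", "N02")
PAIN_EXACT = ("N03AX12", "N03AX16")

#: Amitriptyline / imipramine — the two tricyclics the bed-wetting rule targets.
BEDWETTING_TCAS = ("N06AA09", "N06AA02")

DRUG_NAMES = {
    "N06AA02": "imipramine",
    "N06AA04": "clomipramine",
    "N06AA09": "amitriptyline",
    "N06AA10": "nortriptyline",
    "N06AB03": "fluoxetine",
    "N06AB04": "citalopram",
    "N06AB05": "paroxetine",
    "N06AB06": "sertraline",
    "N06AB08": "fluvoxamine",
    "N06AB10": "escitalopram",
    "N06AX03": "mianserin",
    "N06AX05": "trazodone",
    "N06AX11": "mirtazapine",
    "N06AX16": "venlafaxine",
    "N06AX21": "duloxetine",
}

ATC_BY_NAME = {name: atc for atc, name in DRUG_NAMES.items()}

#: Liquid-concentrate correction applies to these substances only.
LIQUID_CONCENTRATE_ATCS = ("N06AB04", "N06AB10")  # citalopram, escitalopram


class MalformedAtcError(ValueError):
    """Raised when a string is not a syntactically valid ATC code."""


def validate_atc(atc_code: str) -> str:
    """Return the code unchanged if it is a syntactically valid ATC string."""
    if not isinstance(atc_code, str) or not ATC_PATTERN.match(atc_code):
        raise MalformedAtcError(f"malformed ATC code: {atc_code!r}")
    return atc_code


def is_antidepressant(atc_code: str) -> bool:
    """True iff the code falls under N06AA, N06AB or N06AX.

    MAOIs (N06AF/N06AG) and everything outside N06A return False.
    Malformed codes raise :class:`MalformedAtcError`.
    """
    validate_atc(atc_code)
    return atc_code.startswith(ANTIDEPRESSANT_PREFIXES)


def drug_name(atc_code: str) -> str:
    """Human-readable substance name, falling back to the code itself."""
    return DRUG_NAMES.get(atc_code, atc_code)
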