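"""Small bundled datasets and tally helpers.

``field_screen_counts`` reproduces the published field-screening table for
the duplication diagnostic: mosquitoes from ten West African collection sites
were first phenotyped at the target locus (SS / RS / RR) and then tested with
the junction-spanning diagnostic PCR.  Counts are individuals per
(site, phenotype) cell together with the diagnostic outcome of that cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["field_screen_counts", "duplication_tally", "DuplicationTally"]

# (country, site, phenotype, junction_positive, n); cells with n == 0 omitted
_FIELD_SCREEN = [
    ("Benin", "Grand-Popo", "SS", False, 56),
    ("Benin", "Grand-Popo", "RS", True, 7),
    ("Benin", "Natitingou", "SS", False, 54),
    ("Benin", "Natitingou", "RS", True, 5),
    ("Benin", "Natitingou", "RR", True, 1),
    ("Burkina Faso", "VK7", "SS", False, 18),
    ("Burkina Faso", "VK7", "RS", True, 1),
    ("Burkina Faso", "Boromo", "SS", False, 17),
    ("Burkina Faso", "Boromo", "RS", True, 8),
    ("Burkina Faso", "Dano", "SS", False, 26),
    ("Burkina Faso", "Dano", "RS", True, 4),
    ("Burkina Faso", "Bobodioulasso", "SS", False, 43),
    ("Burkina Faso", "Bobodioulasso", "RS", True, 3),
    ("Togo", "Baguida", "RS", True, 11),
    ("Togo", "Baguida", "RR", True, 52),
    ("Ivory Coast", "Tiassale", "RS", True, 43),
    ("Ivory Coast", "Toumodi", "SS", False, 11),
    ("Ivory Coast", "Bouake", "RS", True, 38),
]


def field_screen_counts() -> pd.DataFrame:
    """The bundled field-screening counts as a tidy table."""
    return pd.DataFrame(
        _FIELD_SCREEN,
        columns=["country", "site", "phenotype", "junction_positive", "n"],
    )


@dataclass(frozen=True)
class DuplicationTally:
    """Cross-tabulation of resistance phenotype x junction-diagnostic outcome."""

    crosstab: pd.DataFrame
    resistant_positive: int  # RS or RR individuals with a junction product
    susceptible_negative: int  # SS individuals without one
    discordant: pd.DataFrame  # resistant cells lacking a junction product


def duplication_tally(table: pd.DataFrame) -> DuplicationTally:
    """Cross-tabulate phenotype against the junction diagnostic.

    Flags any resistant ([RS]/[RR]) cell lacking a junction product --
    under the single-shared-amplicon model every resistant individual should
    carry the tandem junction.
    """
    required = {"phenotype", "junction_positive", "n"}
    if not required <= set(table.columns):
        raise ValueError(f"tally table needs columns {sorted(required)}")
    ct = table.pivot_table(
        index="phenotype", columns="junction_positive", values="n",
        aggfunc="sum", fill_value=0,
    )
    resistant = table["phenotype"].isin(("RS", "RR"))
    resistant_positive = int(table.loc[resistant & table["junction_positive"], "n"].sum())
    susceptible_negative = int(
        table.loc[(table["phenotype"] == "SS") & ~table["junction_positive"], "n"].sum()
    )
    discordant = table.loc[resistant & ~table["junction_positive"] & (table["n"] > 0)]
    return DuplicationTally(ct, resistant_positive, susceptible_negative, discordant)
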