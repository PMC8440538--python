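"""Built-in demonstration exposure pathways for simulations and examples.

These mirror the xenobiotic pathways most often seen in untargeted human
studies: nicotine with its oxidative metabolites and glucuronide, and five
common drugs each with characteristic phase I/II products.  Metabolites are
expressed as chains of transformation-rule names applied to the parent
formula, so their theoretical masses always stay consistent with the rule
table.
"""

from __future__ import annotations

from .chem import parse_formula
from .simulate import PathwaySpec

__all__ = ["nicotine_pathway", "drug_pathways", "demo_pathways"]


def nicotine_pathway(n_exposed: int = 7) -> PathwaySpec:
    """Nicotine and its major metabolites.

    Cotinine is net +O −2H from nicotine; hydroxycotinine adds another
    oxygen; the glucuronide conjugates the parent directly.
    """
    return PathwaySpec(
        precursor="nicotine",
        parent_formula=parse_formula("C10H14N2"),
        metabolites={
            "cotinine": ("hydroxylation", "dehydrogenation"),
            "hydroxycotinine": (
                "hydroxylation", "dehydrogenation", "hydroxylation"
            ),
            "nicotine glucuronide": ("glucuronidation",),
        },
        n_exposed=n_exposed,
    )


def drug_pathways() -> list[PathwaySpec]:
    """Five drug pathways, each a parent with expected metabolites.

    Exposure prevalences are plausible for a general adult cohort of ~120
    (a handful of users per common medication).
    """
    return [
        PathwaySpec(
            precursor="bupropion",
            parent_formula=parse_formula("C13H18ClNO"),
            metabolites={
                "hydroxybupropion": ("hydroxylation",),
                "hydrobupropion": ("reduction",),
            },
            n_exposed=9,
        ),
        PathwaySpec(
            precursor="acetaminophen",
            parent_formula=parse_formula("C8H9NO2"),
            metabolites={
                "acetaminophen sulfate": ("sulfation",),
                "acetaminophen glucuronide": ("glucuronidation",),
            },
            n_exposed=12,
        ),
        PathwaySpec(
            precursor="metoprolol",
            parent_formula=parse_formula("C15H25NO3"),
            metabolites={
                "hydroxymetoprolol": ("hydroxylation",),
                "O-desmethylmetoprolol": ("demethylation",),
            },
            n_exposed=10,
        ),
        PathwaySpec(
            precursor="carvedilol",
            parent_formula=parse_formula("C24H26N2O4"),
            metabolites={"hydroxycarvedilol": ("hydroxylation",)},
            n_exposed=8,
        ),
        PathwaySpec(
            precursor="warfarin",
            parent_formula=parse_formula("C19H16O4"),
            metabolites={"hydroxywarfarin": ("hydroxylation",)},
            n_exposed=6,
        ),
    ]


def demo_pathways() -> list[PathwaySpec]:
    """Nicotine plus the five drug pathways."""
    return [nicotine_pathway()] + drug_pathways()
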