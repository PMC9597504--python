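"""Bundled reference data for the rose fragrance pipeline.

Small, hand-curated tables that the analysis and the synthetic-data
generator share:

* the chemical-class summary of the volatile survey of three *Rosa rugosa*
  cultivars (compound counts and summed headspace concentrations per class),
* the 16-compound targeted fragrance panel used for germplasm comparison,
* an illustrative three-criterion evaluation hierarchy for industry
  application scoring (quality / vigor / harvestability),
* a toy compound-to-pathway annotation map covering the monoterpenoid,
  sesquiterpene/triterpene, terpenoid-backbone and phenylpropanoid routes.

The hierarchy and annotation map are illustrative examples: local weights
outside the published criterion weights are filled uniformly, and the
annotation is a small curated map, not a database mirror.
"""

from __future__ import annotations

import pandas as pd

#: Chemical-class summary of the volatile survey: class, number of
#: compounds, summed concentration (µg/L) over all cultivar x stage samples.
VOC_CLASS_SUMMARY = pd.DataFrame(
    [
        ("Monoterpenes", 63, 1.18e9),
        ("Esters", 16, 9.51e7),
        ("Heterocyclic compounds", 10, 1.59e8),
        ("Alkene", 5, 1.10e7),
        ("Alkane", 18, 3.11e7),
        ("Ketones", 12, 2.98e8),
        ("Acids", 2, 8.14e6),
        ("Aldehydes", 10, 1.14e8),
        ("Phenols", 7, 1.76e8),
        ("Aromatic hydrocarbons", 17, 5.27e7),
        ("Alcohols", 10, 7.46e8),
        ("Amines", 1, 5.48e5),
        ("Others", 2, 1.54e7),
        ("Sulfides", 1, 5.38e5),
    ],
    columns=["compound_class", "n_compounds", "concentration_ugL"],
)


def voc_class_table() -> pd.DataFrame:
    """Class summary with the proportion column recomputed from concentrations.

    Proportions are percentages of the summed concentration, so they add to
    exactly 100 by construction.
    """
    t = VOC_CLASS_SUMMARY.copy()
    t["proportion_pct"] = 100.0 * t["concentration_ugL"] / t["concentration_ugL"].sum()
    return t


#: The 16 targeted fragrance compounds (compound -> chemical class):
#: 8 terpenes, 4 esters, 2 phenols, 1 alcohol, 1 heterocyclic compound.
PANEL_COMPOUNDS: dict[str, str] = {
    "alpha-farnesene": "terpene",
    "nerolidol": "terpene",
    "nerol": "terpene",
    "farnesol": "terpene",
    "rose oxide": "terpene",
    "citronellal": "terpene",
    "citronellol": "terpene",
    "linalool": "terpene",
    "neryl acetate": "ester",
    "citronellyl acetate": "ester",
    "phenethyl acetate": "ester",
    "geranyl acetate": "ester",
    "eugenol": "phenol",
    "methyleugenol": "phenol",
    "phenethyl alcohol": "alcohol",
    "trans-linalool oxide": "heterocyclic",
}

#: Published criterion weights of the evaluation hierarchy: quality traits,
#: vigor status, harvest difficulty.
CRITERION_WEIGHTS = {"B1": 0.6370, "B2": 0.2583, "B3": 0.1047}

#: Published local weight of the first quality-trait index under B1.
F1_LOCAL_WEIGHT = 0.0645


def example_hierarchy() -> dict:
    """Illustrative 22-index evaluation hierarchy.

    Three criteria carry the published weights (quality 0.6370, vigor
    0.2583, harvestability 0.1047). Index F1 carries its published local
    weight 0.0645 under B1; the remaining local weights in each criterion
    are uniform so that each block sums to one. Intended as a worked
    example and template, not as a reconstruction of any expert consensus.
    """
    b1_leaves = [f"F{i}" for i in range(1, 9)]  # quality: 3 traits + 5 metabolites
    b2_leaves = [f"F{i}" for i in range(9, 18)]  # vigor: growth traits
    b3_leaves = [f"F{i}" for i in range(18, 23)]  # harvestability: thorn traits
    rest = (1.0 - F1_LOCAL_WEIGHT) / (len(b1_leaves) - 1)
    hierarchy = {
        "goal": "industry application evaluation",
        "criteria": {
            "B1": {
                "name": "quality trait evaluation",
                "weight": CRITERION_WEIGHTS["B1"],
                "indices": {leaf: (F1_LOCAL_WEIGHT if leaf == "F1" else rest) for leaf in b1_leaves},
            },
            "B2": {
                "name": "vigor status evaluation",
                "weight": CRITERION_WEIGHTS["B2"],
                "indices": {leaf: 1.0 / len(b2_leaves) for leaf in b2_leaves},
            },
            "B3": {
                "name": "harvest difficulty evaluation",
                "weight": CRITERION_WEIGHTS["B3"],
                "indices": {leaf: 1.0 / len(b3_leaves) for leaf in b3_leaves},
            },
        },
    }
    return hierarchy


#: Toy pathway annotation: pathway id -> (name, member compounds).
TOY_ANNOTATION: dict[str, tuple[str, tuple[str, ...]]] = {
    "ko00902": (
        "Monoterpenoid biosynthesis",
        (
            "citronellol",
            "nerol",
            "geraniol",
            "linalool",
            "myrcene",
            "alpha-terpineol",
            "(-)-beta-pinene",
        ),
    ),
    "ko00909": (
        "Sesquiterpenoid and triterpenoid biosynthesis",
        ("alpha-farnesene", "nerolidol", "farnesol"),
    ),
    "ko00900": (
        "Terpenoid backbone biosynthesis",
        ("farnesol", "geraniol"),
    ),
    "ko00940": (
        "Phenylpropanoid biosynthesis",
        ("eugenol", "methyleugenol", "isoeugenol"),
    ),
    "ko00400": (
        "Phenylalanine, tyrosine and tryptophan biosynthesis",
        ("phenethyl alcohol", "phenylalanine", "eugenol", "methyleugenol", "isoeugenol"),
    ),
}


def toy_annotation_frame() -> pd.DataFrame:
    """Annotation map as a long table (pathway_id, pathway_name, compound)."""
    rows = [
        (pid, name, compound)
        for pid, (name, members) in TOY_ANNOTATION.items()
        for compound in members
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "compound"])


#: The 17 recorded morphological characters (name -> kind).
TRAIT_DEFINITIONS: dict[str, str] = {
    "petal_type_double": "binary",  # single (0) vs double (1) petals
    "petal_number": "continuous",
    "flower_diameter_cm": "continuous",
    "branch_number": "continuous",
    "plant_morphology": "ordinal",
    "pedicel_length_cm": "continuous",
    "internode_length_cm": "continuous",
    "crown_width_cm": "continuous",
    "main_stem_thickness_mm": "continuous",
    "flowering_branch_thickness_mm": "continuous",
    "plant_height_cm": "continuous",
    "thorn_number": "continuous",
    "thorn_base_shape": "ordinal",
    "thorns_on_flowering_branch": "binary",
    "bristles_on_flowering_branch": "binary",
    "thorns_on_pedicel": "binary",
    "bristles_on_pedicel": "binary",
}
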