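"""Synthetic study generator.

Emulates every input of the pipeline with the statistical structure the
downstream analysis assumes:

* a germplasm collection of 77 accessions (27 rugosa cultivars, 43 scented
  hybrida cultivars, 7 fragrant species) with 17 morphological characters
  sampled from group-conditional Gaussian/Bernoulli/categorical models;
* a 16-compound targeted fragrance panel (µg/g) from a zero-inflated
  log-normal model, group-conditional so that rugosa accessions carry the
  richest scent profile;
* a long-format volatile survey of 3 cultivars x 4 flower-development
  stages x 3 replicates over ~174 compounds, built as
  ``base x stage-archetype x planted-effect x log-normal noise``;
* expert pairwise-comparison (judgment) matrices perturbed around a true
  weight vector.

All generators are pure functions of (design, seed): the design's ``seed``
feeds a :class:`numpy.random.SeedSequence` and each generator draws from
its own spawned stream, so tables are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .errors import ValidationError

_STREAMS = {"traits": 0, "panel": 1, "voc": 2, "judgment": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# germplasm collection: traits and targeted panel


@dataclass(frozen=True)
class TraitModel:
    """Sampling model for one trait in one group.

    ``kind`` is ``continuous`` (Normal(mean, sd) truncated at 0), ``binary``
    (Bernoulli(p), p in ``mean``) or ``ordinal`` (categorical over small
    integer codes with probabilities ``probs``).
    """

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    probs: tuple[float, ...] = ()


def _default_trait_models() -> dict[str, dict[str, TraitModel]]:
    """Group-conditional defaults echoing the field contrasts between
    rugosa, garden hybrids and wild species (hybrids: more/larger petals,
    longer pedicels; rugosa: thornier, shorter internodes)."""
    c, b, o = "continuous", "binary", "ordinal"
    base = {
        "petal_type_double": {"rugosa": (b, 0.4), "hybrida": (b, 0.9), "species": (b, 0.2)},
        "petal_number": {"rugosa": (c, 18, 5), "hybrida": (c, 38, 8), "species": (c, 10, 3)},
        "flower_diameter_cm": {"rugosa": (c, 7.0, 1.0), "hybrida": (c, 8.5, 1.2), "species": (c, 6.0, 1.0)},
        "branch_number": {"rugosa": (c, 22, 5), "hybrida": (c, 12, 4), "species": (c, 18, 5)},
        "plant_morphology": {"rugosa": (o, (0.6, 0.3, 0.1)), "hybrida": (o, (0.2, 0.4, 0.4)), "species": (o, (0.5, 0.4, 0.1))},
        "pedicel_length_cm": {"rugosa": (c, 1.8, 0.4), "hybrida": (c, 3.8, 0.6), "species": (c, 2.0, 0.5)},
        "internode_length_cm": {"rugosa": (c, 2.6, 0.5), "hybrida": (c, 4.2, 0.7), "species": (c, 2.8, 0.6)},
        "crown_width_cm": {"rugosa": (c, 120, 25), "hybrida": (c, 90, 20), "species": (c, 140, 30)},
        "main_stem_thickness_mm": {"rugosa": (c, 14, 3), "hybrida": (c, 11, 2.5), "species": (c, 15, 3)},
        "flowering_branch_thickness_mm": {"rugosa": (c, 4.5, 1.0), "hybrida": (c, 4.0, 1.0), "species": (c, 4.8, 1.1)},
        "plant_height_cm": {"rugosa": (c, 150, 30), "hybrida": (c, 110, 25), "species": (c, 170, 35)},
        "thorn_number": {"rugosa": (c, 90, 20), "hybrida": (c, 30, 12), "species": (c, 60, 18)},
        "thorn_base_shape": {"rugosa": (o, (0.7, 0.2, 0.1)), "hybrida": (o, (0.2, 0.5, 0.3)), "species": (o, (0.5, 0.3, 0.2))},
        "thorns_on_flowering_branch": {"rugosa": (b, 0.9), "hybrida": (b, 0.3), "species": (b, 0.7)},
        "bristles_on_flowering_branch": {"rugosa": (b, 0.8), "hybrida": (b, 0.1), "species": (b, 0.5)},
        "thorns_on_pedicel": {"rugosa": (b, 0.7), "hybrida": (b, 0.2), "species": (b, 0.5)},
        "bristles_on_pedicel": {"rugosa": (b, 0.6), "hybrida": (b, 0.1), "species": (b, 0.4)},
    }
    models: dict[str, dict[str, TraitModel]] = {}
    for trait, per_group in base.items():
        models[trait] = {}
        for group, spec_ in per_group.items():
            if spec_[0] == c:
                models[trait][group] = TraitModel(c, mean=spec_[1], sd=spec_[2])
            elif spec_[0] == b:
                models[trait][group] = TraitModel(b, mean=spec_[1])
            else:
                models[trait][group] = TraitModel(o, probs=spec_[1])
    return models


def _default_panel_models() -> dict[str, dict[str, tuple[float, float, float]]]:
    """Per-compound (log_mean, log_sd, zero_probability) by group.

    Rugosa targets are anchored so the marginal mean content (zeros
    included) matches the targeted-panel survey of 27 rugosa cultivars
    (phenethyl alcohol 11.76 µg/g, citronellol 3.76, nerol 1.77, farnesol
    1.27); the other compounds sit below 1 µg/g. Hybrida contents are
    scaled to a quarter with heavier zero-inflation, species to a half.
    """
    log_sd = 0.5
    rugosa_means = {name: 0.5 for name in datasets.PANEL_COMPOUNDS}
    rugosa_means.update(
        {"phenethyl alcohol": 11.76, "citronellol": 3.76, "nerol": 1.77, "farnesol": 1.27}
    )
    pis = {"rugosa": 0.05, "hybrida": 0.30, "species": 0.15}
    scales = {"rugosa": 1.0, "hybrida": 0.25, "species": 0.5}
    models: dict[str, dict[str, tuple[float, float, float]]] = {}
    for name, mean in rugosa_means.items():
        models[name] = {}
        for group in ("rugosa", "hybrida", "species"):
            target = mean * scales[group]
            # marginal mean (1 - pi) exp(mu + sd^2/2) = target
            mu = float(np.log(target / (1.0 - pis[group])) - 0.5 * log_sd**2)
            models[name][group] = (mu, log_sd, pis[group])
    return models


@dataclass(frozen=True)
class StudyDesign:
    """Design of the synthetic germplasm collection."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"rugosa": 27, "hybrida": 43, "species": 7}
    )
    trait_models: dict[str, dict[str, TraitModel]] = field(default_factory=_default_trait_models)
    panel_models: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=_default_panel_models
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be >= 0")
        for compound, per_group in self.panel_models.items():
            for group, (_, log_sd, pi) in per_group.items():
                if log_sd <= 0:
                    raise ValidationError(f"log-sd must be > 0 ({compound}, {group})")
                if not 0.0 <= pi <= 1.0:
                    raise ValidationError(f"zero-inflation probability must be in [0, 1] ({compound}, {group})")

    def accession_ids(self) -> list[tuple[str, str]]:
        prefix = {"rugosa": "RR", "hybrida": "RH", "species": "RS"}
        out = []
        for group in ("rugosa", "hybrida", "species"):
            n = self.group_sizes.get(group, 0)
            out.extend((f"{prefix[group]}{i + 1:02d}", group) for i in range(n))
        return out


def gen_trait_table(design: StudyDesign) -> pd.DataFrame:
    """Sample one row of morphological characters per accession.

    Continuous traits are Normal(mean, sd) truncated below at 0, binary
    traits Bernoulli, ordinal traits categorical over integer codes
    starting at 1. Deterministic given ``design.seed``.
    """
    ids = design.accession_ids()
    if not ids:
        raise ValidationError("empty design: no accessions in any group")
    rng = _rng(design.seed, "traits")
    rows: dict[str, list] = {"accession_id": [i for i, _ in ids], "group": [g for _, g in ids]}
    for trait, per_group in design.trait_models.items():
        values = []
        for _, group in ids:
            m = per_group[group]
            if m.kind == "continuous":
                values.append(max(0.0, float(rng.normal(m.mean, m.sd))) if m.sd > 0 else max(0.0, m.mean))
            elif m.kind == "binary":
                values.append(int(rng.random() < m.mean))
            elif m.kind == "ordinal":
                values.append(int(rng.choice(len(m.probs), p=m.probs)) + 1)
            else:
                raise ValidationError(f"unknown trait kind {m.kind!r}")
        rows[trait] = values
    return pd.DataFrame(rows)


def gen_targeted_panel(design: StudyDesign) -> pd.DataFrame:
    """Sample the accession x compound content table (µg/g).

    Contents are zero with the group's zero-inflation probability, else
    LogNormal(log_mean, log_sd). Undetected compounds are explicit zeros.
    """
    ids = design.accession_ids()
    if not ids:
        raise ValidationError("empty design: no accessions in any group")
    rng = _rng(design.seed, "panel")
    out: dict[str, list] = {"accession_id": [i for i, _ in ids]}
    for compound, per_group in design.panel_models.items():
        values = []
        for _, group in ids:
            mu, log_sd, pi = per_group[group]
            if rng.random() < pi:
                values.append(0.0)
            else:
                values.append(float(rng.lognormal(mu, log_sd)))
        out[compound] = values
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# volatile survey

#: Nine stage archetypes (multiplicative profiles over the four stages):
#: steady rise/fall, late/early steps, single-stage peaks and a mid valley.
DEFAULT_ARCHETYPES: tuple[tuple[float, float, float, float], ...] = (
    (1, 2, 4, 8),  # 1 gradual rise bud -> withering
    (1, 1, 8, 8),  # 2 step up at full blooming
    (1, 8, 8, 1),  # 3 high mid-season plateau
    (1, 2, 8, 2),  # 4 peak at full blooming
    (1, 8, 1, 1),  # 5 early-blooming spike
    (8, 1, 1, 8),  # 6 mid-season valley
    (1, 1, 1, 8),  # 7 withering spike
    (8, 8, 1, 1),  # 8 step down after early blooming
    (8, 4, 2, 1),  # 9 gradual decline
)


@dataclass(frozen=True)
class PlantedEffect:
    """A differential compound planted between two stages of every cultivar.

    ``multiplier`` (> 1) scales the later stage of ``stage_pair`` up
    (``direction='up'``) or down by its reciprocal (``direction='down'``).
    """

    compound: str
    stage_pair: tuple[int, int]  # (earlier, later)
    multiplier: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValidationError("effect multiplier must be > 0")
        if self.direction not in ("up", "down"):
            raise ValidationError("direction must be 'up' or 'down'")


def default_voc_compounds(n: int = 174) -> pd.DataFrame:
    """Compound catalogue (name, class) echoing the chemical-class census
    of the three-cultivar volatile survey.

    Named fragrance compounds (panel and pathway members) come first in
    their class; remaining slots are filled with synthetic names. Class
    counts follow the bundled class summary, trimmed or padded to ``n``.
    """
    named = {
        "Monoterpenes": [
            "citronellol", "nerol", "geraniol", "linalool", "myrcene",
            "alpha-terpineol", "(-)-beta-pinene", "citronellal", "rose oxide",
            "alpha-farnesene", "nerolidol", "farnesol",
        ],
        "Esters": ["geranyl acetate", "neryl acetate", "citronellyl acetate",
                   "phenethyl acetate", "methyl salicylate"],
        "Phenols": ["eugenol", "methyleugenol", "isoeugenol"],
        "Alcohols": ["phenethyl alcohol"],
        "Heterocyclic compounds": ["trans-linalool oxide"],
        "Aldehydes": ["hexanal", "benzeneacetaldehyde"],
        "Alkane": ["tridecane", "pentadecane", "hexadecane"],
        "Aromatic hydrocarbons": ["styrene", "p-xylene"],
    }
    counts = datasets.VOC_CLASS_SUMMARY.set_index("compound_class")["n_compounds"]
    scale = n / counts.sum()
    rows: list[tuple[str, str]] = []
    for cls, count in counts.items():
        quota = max(len(named.get(cls, [])), int(round(count * scale)))
        members = list(named.get(cls, []))
        slug = cls.lower().replace(" ", "_")
        members += [f"{slug}_{i:03d}" for i in range(1, quota - len(members) + 1)]
        rows.extend((m, cls) for m in members[:quota])
    df = pd.DataFrame(rows[:n], columns=["compound", "compound_class"])
    return df


@dataclass(frozen=True)
class VOCDesign:
    """Design of the synthetic volatile survey."""

    cultivars: tuple[str, ...] = ("BZ", "GM", "HX")
    stages: int = 4
    replicates: int = 3
    compounds: pd.DataFrame = field(default_factory=default_voc_compounds)
    archetypes: tuple[tuple[float, ...], ...] = DEFAULT_ARCHETYPES
    planted: tuple[PlantedEffect, ...] = ()
    flat_fraction: float = 0.1  # share of compounds with no stage trend
    noise_sd: float = 0.1  # log-scale sd of replicate noise
    cultivar_scale: dict[str, float] = field(
        default_factory=lambda: {"BZ": 0.5, "GM": 1.0, "HX": 1.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stages != 4:
            raise ValidationError("the survey design covers exactly four flower-development stages")
        for prof in self.archetypes:
            if len(prof) != 4:
                raise ValidationError("archetype profiles must have length 4")
            if any(v <= 0 for v in prof):
                raise ValidationError("archetype profile values must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        if not 0.0 <= self.flat_fraction <= 1.0:
            raise ValidationError("flat_fraction must be in [0, 1]")
        known = set(self.compounds["compound"])
        for eff in self.planted:
            if eff.compound not in known:
                raise ValidationError(f"planted differential references unknown compound {eff.compound!r}")
            s1, s2 = eff.stage_pair
            if not (1 <= s1 <= 4 and 1 <= s2 <= 4 and s1 != s2):
                raise ValidationError(f"invalid stage pair {eff.stage_pair}")


@dataclass(frozen=True)
class VOCSimulation:
    """A generated volatile survey plus its ground truth."""

    records: pd.DataFrame  # long-format VOC table
    archetype_class: pd.Series  # compound -> 1-based archetype index (0 = flat)
    base: pd.Series  # compound -> base concentration (µg/L)


def gen_voc_experiment(design: VOCDesign) -> VOCSimulation:
    """Simulate the cultivar x stage x replicate x compound survey.

    ``concentration = base(compound) x cultivar_scale x archetype(stage)
    x planted_effect(stage) x LogNormal(0, noise_sd)``. Base levels are
    drawn log-uniformly over 1e3-1e6 µg/L so classes span orders of
    magnitude as volatile surveys do. Deterministic given ``design.seed``.
    """
    rng = _rng(design.seed, "voc")
    compounds = design.compounds["compound"].tolist()
    classes = design.compounds["compound_class"].tolist()
    p = len(compounds)
    base = 10.0 ** rng.uniform(3, 6, size=p)
    arch_idx = rng.integers(1, len(design.archetypes) + 1, size=p)  # 1-based
    flat = rng.random(p) < design.flat_fraction
    arch_idx[flat] = 0  # flat compounds carry no stage trend
    profiles = np.where(
        flat[:, None],
        1.0,
        np.asarray(design.archetypes, dtype=float)[np.maximum(arch_idx - 1, 0)],
    )  # p x 4

    effect = np.ones((p, 4))
    pos = {c: i for i, c in enumerate(compounds)}
    for eff in design.planted:
        factor = eff.multiplier if eff.direction == "up" else 1.0 / eff.multiplier
        effect[pos[eff.compound], eff.stage_pair[1] - 1] *= factor

    rows = []
    for cultivar in design.cultivars:
        scale = design.cultivar_scale.get(cultivar, 1.0)
        for stage in range(1, 5):
            for rep in range(1, design.replicates + 1):
                noise = (
                    rng.lognormal(0.0, design.noise_sd, size=p)
                    if design.noise_sd > 0
                    else np.ones(p)
                )
                conc = base * scale * profiles[:, stage - 1] * effect[:, stage - 1] * noise
                rows.append(
                    pd.DataFrame(
                        {
                            "cultivar": cultivar,
                            "stage": stage,
                            "replicate": rep,
                            "compound": compounds,
                            "compound_class": classes,
                            "concentration": conc,
                        }
                    )
                )
    records = pd.concat(rows, ignore_index=True)
    return VOCSimulation(
        records=records,
        archetype_class=pd.Series(arch_idx, index=compounds, name="archetype"),
        base=pd.Series(base, index=compounds, name="base"),
    )


# ---------------------------------------------------------------------------
# expert judgment matrices

_SAATY_SCALE = np.array(
    [1 / 9, 1 / 8, 1 / 7, 1 / 6, 1 / 5, 1 / 4, 1 / 3, 1 / 2, 1, 2, 3, 4, 5, 6, 7, 8, 9]
)


@dataclass(frozen=True)
class JudgmentDesign:
    """Design of the synthetic expert panel.

    Each expert's comparison of items i and j is the true weight ratio
    ``w_i/w_j`` perturbed by a log-normal factor ``exp(delta)``,
    ``delta ~ Normal(0, sigma^2)``; the lower triangle is filled with
    reciprocals so matrices are exactly reciprocal. ``saaty_snap`` rounds
    entries to the nearest value of the discrete 1-9 scale (off by
    default: snapping distorts small-sigma recovery).
    """

    true_weights: tuple[float, ...]
    sigma: float = 0.1
    n_experts: int = 15
    saaty_snap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if (w <= 0).any():
            raise ValidationError("true weights must be > 0")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValidationError("true weights must sum to 1")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.n_experts < 1:
            raise ValidationError("need at least one expert")


def gen_judgment_matrices(design: JudgmentDesign) -> list[np.ndarray]:
    """Simulate one positive reciprocal judgment matrix per expert."""
    rng = _rng(design.seed, "judgment")
    w = np.asarray(design.true_weights, dtype=float)
    n = len(w)
    matrices = []
    for _ in range(design.n_experts):
        a = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                val = (w[i] / w[j]) * float(np.exp(rng.normal(0.0, design.sigma)))
                if design.saaty_snap:
                    val = float(_SAATY_SCALE[np.argmin(np.abs(_SAATY_SCALE - val))])
                a[i, j] = val
                a[j, i] = 1.0 / val
        matrices.append(a)
    return matrices


def with_seed(design, seed: int):
    """Return a copy of any design with its seed replaced."""
    return replace(design, seed=int(seed))
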