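"""Synthetic NF-κB-style compound libraries.

The generator emulates the statistical shape of the curated literature
library the protocol was designed around: six interaction classes with
heavily skewed frequencies (IKK inhibitors dominate), a large block of
compounds whose point of interaction is unknown, a handful of dual-label
compounds, and — crucially — *structurally coherent series*: compounds come
in families of close analogues, so the similar-property principle has
something to grip.  Unknown-interaction compounds form coherent series of
their own (drawn from a randomly chosen class's structure generator but
carrying no label), emulating unstudied analogue series rather than
uniform structural noise.

Two fidelity levels share the same series plan:

* :func:`generate_fp_library` — abstract fingerprint space.  Each series
  has a prototype feature set (fixed cardinality, disjointly seeded) and
  each member copies it with per-feature noise ε: prototype features drop
  out with probability ε and a Binomial(cardinality, ε) count of fresh
  features is added.  This exercises the whole clustering/prediction stack
  without any chemistry.
* :func:`generate_library` — valid SMILES.  Each series is a scaffold
  template with fixed ring substituents and one variable position
  enumerated over a substituent alphabet; dual-label compounds are two
  series members joined by a single bond.

Default sizes are the class marginals of the real library (dual-label
compounds count toward both of their classes, so the compound total is
Σ class_counts + unknown_count − dual_label_count = 460 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import CompoundRecord, InteractionLabel, parse_smiles
from .descriptors import DescriptorSet, DescriptorVector, circular_fingerprint

#: Class marginals of the curated library (training + test of dataset 1).
DEFAULT_CLASS_COUNTS: dict[InteractionLabel, int] = {
    InteractionLabel.ROS: 14,
    InteractionLabel.TRANSLOCATION_INHIBITION: 7,
    InteractionLabel.DNA_BINDING: 60,
    InteractionLabel.IKK_INHIBITION: 138,
    InteractionLabel.IKB_DEG_INHIBITION: 76,
    InteractionLabel.IKB_DEG_ACTIVATION: 6,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generated library.

    ``series_size`` is the target number of analogues per structural
    series (8 by default: a typical published analogue-series size, small
    enough that every class, even the 6-compound one, forms at least one
    coherent series).  ``noise_rate`` is the per-feature corruption
    probability ε within a series.
    """

    class_counts: dict[InteractionLabel, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    unknown_count: int = 163
    dual_label_count: int = 4
    series_size: int = 8
    noise_rate: float = 0.05
    rng_seed: int = 0
    prototype_cardinality: int = 48

    def __post_init__(self):
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if self.unknown_count < 0 or self.dual_label_count < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.noise_rate <= 0.5:
            raise ValueError("noise_rate must be in [0, 0.5]")
        if self.series_size < 1:
            raise ValueError("series_size must be >= 1")
        n_usable = sum(1 for c in self.class_counts.values() if c >= 1)
        if self.dual_label_count > 0 and n_usable < 2:
            raise ValueError("dual-label compounds need >= 2 populated classes")

    @property
    def total_compounds(self) -> int:
        return (
            sum(self.class_counts.values())
            + self.unknown_count
            - self.dual_label_count
        )


@dataclass(frozen=True)
class _Series:
    index: int
    label: InteractionLabel | None  # None -> unknown-interaction series
    source_class: InteractionLabel  # whose structure generator produced it
    size: int


@dataclass
class _Plan:
    series: list[_Series]
    dual_pairs: list[tuple[InteractionLabel, InteractionLabel]]


def _plan(cfg: SyntheticConfig, rng: np.random.Generator) -> _Plan:
    classes = [c for c in InteractionLabel if cfg.class_counts.get(c, 0) > 0]
    # dual-label compounds consume one slot in each of two distinct classes
    dual_pairs: list[tuple[InteractionLabel, InteractionLabel]] = []
    remaining = {c: cfg.class_counts.get(c, 0) for c in classes}
    for _ in range(cfg.dual_label_count):
        avail = [c for c in classes if remaining[c] > 0]
        if len(avail) < 2:
            raise ValueError("not enough class slots for dual-label compounds")
        weights = np.array([remaining[c] for c in avail], dtype=float)
        pick = rng.choice(len(avail), size=2, replace=False, p=weights / weights.sum())
        a, b = avail[int(pick[0])], avail[int(pick[1])]
        remaining[a] -= 1
        remaining[b] -= 1
        dual_pairs.append((a, b))

    series: list[_Series] = []
    for cls in classes:
        left = remaining[cls]
        while left > 0:
            size = min(cfg.series_size, left)
            series.append(_Series(len(series), cls, cls, size))
            left -= size
    left = cfg.unknown_count
    while left > 0:
        size = min(cfg.series_size, left)
        source = classes[int(rng.integers(len(classes)))] if classes else None
        series.append(_Series(len(series), None, source, size))
        left -= size
    return _Plan(series=series, dual_pairs=dual_pairs)


# ---------------------------------------------------------------------------
# fingerprint-space generator

_FEATURE_SPACE = 2**31


def _noisy_copy(
    prototype: frozenset[int], eps: float, rng: np.random.Generator
) -> frozenset[int]:
    kept = {f for f in sorted(prototype) if rng.random() >= eps}
    n_extra = rng.binomial(len(prototype), eps)
    extra = {int(x) for x in rng.integers(0, _FEATURE_SPACE, size=n_extra)}
    return frozenset(kept | extra)


def generate_fp_library(
    cfg: SyntheticConfig,
) -> tuple[list[CompoundRecord], dict[str, DescriptorVector]]:
    """Abstract fingerprint-space library: records plus feature-set vectors.

    Fully reproducible from ``cfg.rng_seed``.  Records carry placeholder
    SMILES (``*``) because no chemistry is involved at this fidelity level.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    plan = _plan(cfg, rng)
    prototypes: dict[int, frozenset[int]] = {
        s.index: frozenset(
            int(x) for x in rng.integers(0, _FEATURE_SPACE, size=cfg.prototype_cardinality)
        )
        for s in plan.series
    }
    records: list[CompoundRecord] = []
    vectors: dict[str, DescriptorVector] = {}

    def add(cid: str, labels: frozenset[InteractionLabel], fp: frozenset[int], note: str):
        records.append(
            CompoundRecord(compound_id=cid, smiles="*", labels=labels, source_note=note)
        )
        vectors[cid] = DescriptorVector(set_id=DescriptorSet.ECFP4, fingerprint=fp)

    counter = 0
    for s in plan.series:
        labels = frozenset({s.label}) if s.label is not None else frozenset()
        for _ in range(s.size):
            counter += 1
            fp = _noisy_copy(prototypes[s.index], cfg.noise_rate, rng)
            add(
                f"cmpd_{counter:04d}",
                labels,
                fp,
                f"series={s.index} class={s.source_class.value if s.source_class else 'NA'}",
            )
    series_of_class: dict[InteractionLabel, list[int]] = {}
    for s in plan.series:
        if s.label is not None:
            series_of_class.setdefault(s.label, []).append(s.index)
    for a, b in plan.dual_pairs:
        counter += 1
        sa = series_of_class[a][int(rng.integers(len(series_of_class[a])))]
        sb = series_of_class[b][int(rng.integers(len(series_of_class[b])))]
        union = prototypes[sa] | prototypes[sb]
        add(
            f"cmpd_{counter:04d}",
            frozenset({a, b}),
            _noisy_copy(union, cfg.noise_rate, rng),
            f"dual series={sa}+{sb}",
        )
    return records, vectors


# ---------------------------------------------------------------------------
# SMILES generator

#: Scaffold templates: aromatic cores with three substitution sites.  All
#: sites hang off aromatic carbons so any alphabet entry is valid there.
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "c1c({0})cc({1})cc1{2}",                      # benzene, 1,3,5
    "c1cc({0})c(O)c(C(=O)O{1})c1{2}",             # salicylate-like
    "c1cc({0})nc({1})c1{2}",                      # pyridine
    "c1cc({0})c2cc({1})ccc2c1{2}",                # naphthalene
    "c1cc({0})ccc1-c1cc({1})ccc1{2}",             # biphenyl
    "c1cc({0})ccc1/C=C/c1cc({1})cc(O)c1{2}",      # stilbene (resveratrol-like)
    "c1cc({0})ccc1C(=O)Nc1cc({1})ccc1{2}",        # benzanilide
    "c1cc({0})cc({2})c1-c1nc2cc({1})ccc2o1",      # benzoxazole
    "c1cc({0})ccc1S(=O)(=O)Nc1cc({1})ccc1{2}",    # sulfonanilide
    "c1cc({0})ccc1Cc1cc({1})ccc1{2}",             # diphenylmethane
    "c1cc({0})ccc1-c1cc({1})nn1-c1ccc({2})cc1",   # pyrazole-diaryl
    "c1cc({0})ccc1Oc1cc({1})ccc1{2}",             # diphenyl ether
    "c1cc({0})ccc1-c1nc2cc({1})cc({2})c2[nH]1",   # 2-arylbenzimidazole
    "c1cc({0})ccc1C(=O)c1cc({1})ccc1{2}",         # benzophenone
    "c1cc({0})ccc1N=Nc1cc({1})ccc1{2}",           # azobenzene
)

#: Ring-substituent alphabet used to fill template sites.
SUBSTITUENT_ALPHABET: tuple[str, ...] = (
    "C", "O", "N", "F", "Cl", "Br", "I", "CC", "OC", "C(C)C",
    "C#N", "C(F)(F)F", "CCO", "NC", "C(=O)C", "OCC",
)


def _render(template: str, subs: Sequence[str]) -> str:
    return template.format(*subs)


def _link_molecules(smiles_a: str, smiles_b: str) -> str:
    """Join two molecules with a single bond between aromatic CH atoms."""
    mol_a, mol_b = parse_smiles(smiles_a), parse_smiles(smiles_b)

    def attach_atom(mol: Chem.Mol) -> int:
        for atom in mol.GetAtoms():
            if atom.GetIsAromatic() and atom.GetSymbol() == "C" and atom.GetTotalNumHs() > 0:
                return atom.GetIdx()
        raise ValueError("no aromatic CH available as an attachment point")

    ia, ib = attach_atom(mol_a), attach_atom(mol_b)
    combo = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    combo.AddBond(ia, mol_a.GetNumAtoms() + ib, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_library(cfg: SyntheticConfig) -> list[CompoundRecord]:
    """SMILES scaffold-series library with the same plan as the fp version.

    Every output parses; series are (template, fixed substituents)
    families whose members vary one ring position over the alphabet.
    """
    if cfg.series_size > len(SUBSTITUENT_ALPHABET):
        raise ValueError(
            f"series_size {cfg.series_size} exceeds the substituent alphabet "
            f"({len(SUBSTITUENT_ALPHABET)}); extend SUBSTITUENT_ALPHABET to "
            "enumerate larger series"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    plan = _plan(cfg, rng)

    used_series_keys: set[tuple[int, str, str]] = set()
    series_members: dict[int, list[str]] = {}
    for s in plan.series:
        for _attempt in range(1000):
            tmpl_i = int(rng.integers(len(SCAFFOLD_TEMPLATES)))
            fixed = tuple(
                SUBSTITUENT_ALPHABET[int(rng.integers(len(SUBSTITUENT_ALPHABET)))]
                for _ in range(2)
            )
            key = (tmpl_i, *fixed)
            if key not in used_series_keys:
                used_series_keys.add(key)
                break
        else:
            raise ValueError(
                "could not draw a fresh scaffold/substituent series; extend "
                "SCAFFOLD_TEMPLATES or SUBSTITUENT_ALPHABET"
            )
        variable = list(SUBSTITUENT_ALPHABET)
        rng.shuffle(variable)
        members = []
        for v in variable[: s.size]:
            smiles = _render(SCAFFOLD_TEMPLATES[tmpl_i], (fixed[0], fixed[1], v))
            parse_smiles(smiles)  # contract: every generated SMILES parses
            members.append(smiles)
        series_members[s.index] = members

    records: list[CompoundRecord] = []
    counter = 0
    for s in plan.series:
        labels = frozenset({s.label}) if s.label is not None else frozenset()
        for smiles in series_members[s.index]:
            counter += 1
            records.append(
                CompoundRecord(
                    compound_id=f"cmpd_{counter:04d}",
                    smiles=smiles,
                    labels=labels,
                    source_note=f"series={s.index} "
                    f"class={s.source_class.value if s.source_class else 'NA'}",
                )
            )
    series_of_class: dict[InteractionLabel, list[int]] = {}
    for s in plan.series:
        if s.label is not None:
            series_of_class.setdefault(s.label, []).append(s.index)
    for a, b in plan.dual_pairs:
        counter += 1
        sa = series_of_class[a][int(rng.integers(len(series_of_class[a])))]
        sb = series_of_class[b][int(rng.integers(len(series_of_class[b])))]
        smiles = _link_molecules(series_members[sa][0], series_members[sb][0])
        records.append(
            CompoundRecord(
                compound_id=f"cmpd_{counter:04d}",
                smiles=smiles,
                labels=frozenset({a, b}),
                source_note=f"dual series={sa}+{sb}",
            )
        )
    return records
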