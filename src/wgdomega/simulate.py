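"""Synthetic WGD orthogroups: trees, codon alignments, and property tables.

The generator emulates the study design of yeast post-WGD orthogroups: a
backbone of non-WGD outgroup species, a WGD node below which the post-WGD
species subtree is duplicated into paralogous clades A and B, and codon
sequences evolved forward under the branch-class codon model.  Scenarios
encode the classic post-duplication rate dynamics: a symmetric burst of
accelerated evolution on the immediate post-WGD branches, followed by a
deceleration that may or may not differ between the clades.

Default scenario omegas sit inside realistic yeast ranges (non-WGD dN/dS
mostly well below 0.2, post-WGD rates around 0.1-0.5); branch lengths are
exponential with mean 0.15 substitutions/codon.  Everything is a pure
function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, CodonFrequencies
from .codonmodel import CLASS_ORDER, _ClassModel
from .genetics import GeneticCode
from .orthogroups import Orthogroup
from .trees import SpeciesTopology, TreeNode, label_branches

SCENARIO_NAMES = (
    "constant",
    "symmetric_shift",
    "accel_then_decel",
    "asymmetric_decel",
    "asymmetric_immediate",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation condition: true omegas per branch class plus sizes.

    ``branch_length_law`` is ``("exponential", mean)``; lengths are drawn
    i.i.d. per branch in expected substitutions per codon.
    """

    name: str
    omega_by_class: Mapping[str, float]
    kappa: float = 2.0
    n_codons: int = 300
    n_postwgd_species: int = 5
    n_nonwgd_species: int = 3
    branch_length_law: tuple[str, float] = ("exponential", 0.15)
    seed: int = 0

    def __post_init__(self):
        om = dict(self.omega_by_class)
        object.__setattr__(self, "omega_by_class", om)
        if set(om) != set(CLASS_ORDER):
            raise ValueError(f"omega_by_class must cover {CLASS_ORDER}")
        if any(v < 0 for v in om.values()):
            raise ValueError("omegas must be non-negative")
        if self.name == "constant" and len(set(om.values())) != 1:
            raise ValueError("constant scenario requires equal omegas")
        if self.name == "asymmetric_decel":
            if om["a1"] != om["b1"] or om["a2"] == om["b2"]:
                raise ValueError(
                    "asymmetric_decel requires a1 == b1 and a2 != b2"
                )

    def replace(self, **kw) -> "ScenarioSpec":
        return replace(self, **kw)


def _omegas(o0, oa1, ob1, oa2, ob2):
    return {"0": o0, "a1": oa1, "b1": ob1, "a2": oa2, "b2": ob2}


#: default parameter sets for the scenario taxonomy
SCENARIOS: dict[str, ScenarioSpec] = {
    "constant": ScenarioSpec("constant", _omegas(0.1, 0.1, 0.1, 0.1, 0.1)),
    "symmetric_shift": ScenarioSpec(
        "symmetric_shift", _omegas(0.05, 0.3, 0.3, 0.3, 0.3)
    ),
    "accel_then_decel": ScenarioSpec(
        "accel_then_decel", _omegas(0.05, 0.4, 0.4, 0.15, 0.15)
    ),
    "asymmetric_decel": ScenarioSpec(
        "asymmetric_decel", _omegas(0.1, 0.4, 0.4, 0.1, 0.5)
    ),
    "asymmetric_immediate": ScenarioSpec(
        "asymmetric_immediate", _omegas(0.1, 0.15, 0.6, 0.2, 0.2)
    ),
}


def scenario(name: str, **overrides) -> ScenarioSpec:
    """A default scenario, optionally with field overrides."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")
    spec = SCENARIOS[name]
    return spec.replace(**overrides) if overrides else spec


# ---------------------------------------------------------------------------
# Topology generation
# ---------------------------------------------------------------------------


def _draw_length(law: tuple[str, float], rng: np.random.Generator) -> float:
    kind, param = law
    if kind == "exponential":
        return float(rng.exponential(param))
    if kind == "fixed":
        return float(param)
    raise ValueError(f"unknown branch-length law {kind!r}")


def _random_subtree(names: list[str], law, rng) -> TreeNode:
    """Random bifurcating tree by successive joins; lengths drawn from law."""
    nodes = [TreeNode(n, _draw_length(law, rng)) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(None, _draw_length(law, rng), children=[a, b]))
    return nodes[0]


def generate_topology(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[SpeciesTopology, TreeNode]:
    """Species topology plus the true labeled gene tree for one orthogroup.

    The post-WGD species subtree hangs below the WGD node and is duplicated
    into clades A and B in the gene tree; non-WGD species attach as
    successively deeper outgroups (a caterpillar backbone, the shape of the
    yeast species phylogeny).  Leaf names follow ``species|copy|gene``.
    """
    if spec.n_postwgd_species < 1 or spec.n_nonwgd_species < 1:
        raise ValueError("need at least one species on each side of the WGD")
    rng = rng or np.random.default_rng(spec.seed)
    law = spec.branch_length_law
    post = [f"post{i+1}" for i in range(spec.n_postwgd_species)]
    non = [f"out{i+1}" for i in range(spec.n_nonwgd_species)]

    post_sub = _random_subtree(post, law, rng)
    species_tree = post_sub
    for sp in non:
        species_tree = TreeNode(
            None, _draw_length(law, rng), children=[species_tree, TreeNode(sp, _draw_length(law, rng))]
        )
    species_tree.length = None
    topology = SpeciesTopology(tree=species_tree, post_wgd_species=frozenset(post))

    # gene tree: duplicate the post-WGD subtree
    def rename(node: TreeNode, tag: str) -> TreeNode:
        out = TreeNode(None, node.length)
        if node.is_leaf:
            out.name = f"{node.name}|{tag}|g"
        out.children = [rename(c, tag) for c in node.children]
        return out

    def redraw_lengths(node: TreeNode):
        for n in node.postorder():
            if n is not node:
                n.length = _draw_length(law, rng)

    clade_a = rename(post_sub, "A")
    clade_b = rename(post_sub, "B")
    redraw_lengths(clade_b)  # the two clades evolve independently after WGD
    clade_a.length = _draw_length(law, rng)
    clade_b.length = _draw_length(law, rng)
    wgd = TreeNode(None, topology.wgd_node.length, children=[clade_a, clade_b])

    def rebuild(node: TreeNode) -> TreeNode:
        if node is topology.wgd_node:
            return wgd
        out = TreeNode(node.name, node.length)
        if node.is_leaf and node.name in topology.non_wgd_species:
            out.name = f"{node.name}|none|g"
        out.children = [rebuild(c) for c in node.children]
        return out

    gene_tree = rebuild(topology.tree)
    label_branches(gene_tree, wgd, a_child=clade_a)
    return topology, gene_tree


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


def simulate_alignment(
    tree: TreeNode,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
    freqs: CodonFrequencies | None = None,
) -> CodonAlignment:
    """Evolve codon states forward along a labeled tree.

    Root codons are drawn from the equilibrium frequencies; each branch
    applies the exact transition kernel ``P(t)`` of its class's rate matrix
    (distributionally equivalent at the leaves to event-level simulation).
    Stop codons never occur: they are outside the state space.
    """
    rng = rng or np.random.default_rng(spec.seed)
    freqs = freqs or CodonFrequencies.equal()
    code = freqs.code
    models = {
        cls: _ClassModel(freqs.pi, spec.kappa, om, code)
        for cls, om in spec.omega_by_class.items()
    }
    root_states = rng.choice(code.n_states, size=spec.n_codons, p=freqs.pi)
    taxa: list[str] = []
    rows: list[np.ndarray] = []

    def evolve(node: TreeNode, state: np.ndarray) -> None:
        if node.is_leaf:
            taxa.append(node.name)
            rows.append(state)
            return
        for child in node.children:
            cls = child.branch_class
            if cls is None:
                raise ValueError(f"branch above {child.name!r} has no class")
            cum = np.cumsum(models[cls].spec.transition(float(child.length or 0.0)), axis=1)
            u = rng.random(spec.n_codons)
            out = np.empty_like(state)
            for s in np.unique(state):
                mask = state == s
                out[mask] = np.searchsorted(cum[s], u[mask], side="right")
            np.clip(out, 0, code.n_states - 1, out=out)
            evolve(child, out)

    evolve(tree, root_states)
    return CodonAlignment(taxa, np.stack(rows), code)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticOrthogroup:
    """An orthogroup plus the ground truth that generated it."""

    orthogroup: Orthogroup
    truth: ScenarioSpec
    true_tree: TreeNode
    alignment: CodonAlignment


def _alignment_to_orthogroup(
    og_id: str, alignment: CodonAlignment, code: GeneticCode
) -> Orthogroup:
    codons = code.sense_codons
    cds = {}
    proteins = {}
    for i, name in enumerate(alignment.taxa):
        seq = "".join(codons[s] for s in alignment.codons[i])
        cds[name] = seq + "TAA"  # terminal stop, trimmed downstream
        proteins[name] = "".join(code.translate(codons[s]) for s in alignment.codons[i])
    assignment = {}
    for name in alignment.taxa:
        species, tag, _gene = name.split("|")
        assignment[name] = (species, tag)
    return Orthogroup(
        id=og_id,
        cds=cds,
        protein_alignment=proteins,
        assignment=assignment,
        provenance="synthetic",
    )


def generate_orthogroup(
    spec: ScenarioSpec, og_id: str = "og", rng: np.random.Generator | None = None
) -> SyntheticOrthogroup:
    """Generate one synthetic orthogroup (tree + alignment + CDS bundle)."""
    rng = rng or np.random.default_rng(spec.seed)
    _topology, gene_tree = generate_topology(spec, rng)
    alignment = simulate_alignment(gene_tree, spec, rng)
    og = _alignment_to_orthogroup(og_id, alignment, alignment.code)
    return SyntheticOrthogroup(og, spec, gene_tree, alignment)


def generate_cohort(
    n_orthogroups: int,
    scenario_mix: Mapping[str, float],
    template: ScenarioSpec | None = None,
    seed: int = 0,
    overrides: Mapping[str, Mapping] | None = None,
) -> list[SyntheticOrthogroup]:
    """A reproducible cohort with a multinomial mix of scenarios.

    ``template`` overrides sizes (codons, species counts) for every scenario;
    ``overrides`` maps scenario name to per-scenario field overrides.
    """
    mix = dict(scenario_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("scenario proportions must sum to 1")
    names = list(mix)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    draws = rng.choice(len(names), size=n_orthogroups, p=[mix[n] for n in names])
    child_seeds = ss.spawn(n_orthogroups)
    cohort = []
    for k in range(n_orthogroups):
        name = names[draws[k]]
        spec = scenario(name, **(dict(overrides.get(name, {})) if overrides else {}))
        if template is not None:
            spec = spec.replace(
                n_codons=template.n_codons,
                n_postwgd_species=template.n_postwgd_species,
                n_nonwgd_species=template.n_nonwgd_species,
                branch_length_law=template.branch_length_law,
                kappa=template.kappa,
            )
        og_rng = np.random.default_rng(child_seeds[k])
        cohort.append(generate_orthogroup(spec, og_id=f"og{k:04d}", rng=og_rng))
    return cohort


def truth_manifest(cohort: Sequence[SyntheticOrthogroup]) -> pd.DataFrame:
    """Per-orthogroup ground-truth table for recovery scoring."""
    rows = []
    for s in cohort:
        row = {
            "orthogroup": s.orthogroup.id,
            "scenario": s.truth.name,
            "kappa": s.truth.kappa,
            "n_codons": s.truth.n_codons,
            "tree_length": s.true_tree.total_length(),
        }
        for cls in CLASS_ORDER:
            row[f"omega_{cls}"] = s.truth.omega_by_class[cls]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropertyEffects:
    """How synthetic gene properties are generated.

    Categories are drawn per orthogroup with probabilities that depend on
    whether the true scenario changes rate after the WGD — that category ↔
    rate-change association, combined with category-specific property
    levels, reproduces the confound structure in which a property differs
    between verdict classes overall but not within any category.
    ``coupling`` adds a direct multiplicative rate-change effect on
    abundance (0 = property independent of verdict given category).
    """

    category_probs_change: Mapping[str, float] = field(
        default_factory=lambda: {
            "regulatory": 0.35,
            "enzyme": 0.25,
            "ribosomal": 0.05,
            "other": 0.35,
        }
    )
    category_probs_constant: Mapping[str, float] = field(
        default_factory=lambda: {
            "regulatory": 0.08,
            "enzyme": 0.22,
            "ribosomal": 0.35,
            "other": 0.35,
        }
    )
    abundance_median: Mapping[str, float] = field(
        default_factory=lambda: {
            "regulatory": 30.0,
            "enzyme": 200.0,
            "ribosomal": 1000.0,
            "other": 100.0,
        }
    )
    abundance_sigma_log: float = 1.0
    disorder_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "regulatory": 150.0,
            "enzyme": 50.0,
            "ribosomal": 30.0,
            "other": 80.0,
        }
    )
    disorder_dispersion: float = 2.0
    fitness_cost_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "regulatory": 0.02,
            "enzyme": 0.03,
            "ribosomal": 0.12,
            "other": 0.02,
        }
    )
    coupling: float = 0.0


def generate_property_tables(
    cohort: Sequence[SyntheticOrthogroup],
    effects: PropertyEffects | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene property table for the two focal paralogs of each orthogroup.

    Abundance is log-normal around a category-specific median (ppm);
    disorder is negative-binomial; fitness is 1 minus an exponential cost.
    CAI is a noisy decreasing function of the true clade omega, so codon
    adaptation tracks expression-driven bias.
    """
    effects = effects or PropertyEffects()
    rng = np.random.default_rng(seed)
    cats = list(effects.category_probs_change)
    rows = []
    for s in cohort:
        changed = s.truth.name != "constant"
        probs = (
            effects.category_probs_change if changed else effects.category_probs_constant
        )
        category = cats[rng.choice(len(cats), p=[probs[c] for c in cats])]
        focal = sorted(
            name
            for name, (_sp, tag) in s.orthogroup.assignment.items()
            if tag in ("A", "B")
        )[:2]
        for name in focal:
            tag = s.orthogroup.assignment[name][1]
            mu = np.log(effects.abundance_median[category])
            if effects.coupling != 0 and changed:
                mu -= effects.coupling
            abundance = float(rng.lognormal(mu, effects.abundance_sigma_log))
            m = effects.disorder_mean[category]
            r = effects.disorder_dispersion
            disorder = int(rng.negative_binomial(r, r / (r + m)))
            fitness = float(
                1.0 - rng.exponential(effects.fitness_cost_mean[category])
            )
            om = s.truth.omega_by_class["a2" if tag == "A" else "b2"]
            cai = float(np.clip(0.9 - 0.6 * om + rng.normal(0, 0.05), 0.05, 1.0))
            rows.append(
                {
                    "gene": name,
                    "orthogroup": s.orthogroup.id,
                    "copy": tag,
                    "category": category,
                    "abundance": abundance,
                    "disorder_aa": disorder,
                    "fitness": fitness,
                    "cai": cai,
                }
            )
    return pd.DataFrame(rows)
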