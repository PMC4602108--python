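"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
an expression matrix with planted co-expressed modules and a binary
floral/non-floral sample trait, a protein corpus whose interaction status
is encoded in a shared segmental residue composition, subcellular
localization assignments, gene-term annotations with planted
module-enriched terms, and sequence families evolved along a known tree.
All generators are pure functions of their configuration and seed.

The interaction signal works as follows. Each interaction family owns two
residue pools (disjoint slices of a seeded permutation of the 20-residue
alphabet) and a family-specific periodic segment template; a member
sequence samples residues independently from the pool dictated by the
template at each position. Members of one family therefore share a
segmental composition that the lagged auto-covariance encoder picks up,
while the family templates and pools keep different families apart.
``signal_strength`` linearly mixes the pools with the uniform background
composition; at 0 every protein is an i.i.d. uniform sequence and the
classes are indistinguishable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from io import StringIO
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Phylo

from .config import SimulationConfig
from .coexpression import ExpressionData
from .ppi import ProteinRecord
from .properties import AMINO_ACIDS

# rng stream tags (mixed with the config seed via SeedSequence spawning)
_STREAM_EXPR = 11
_STREAM_PROFILES = 12
_STREAM_SEQS = 13
_STREAM_ANNOT = 14
_STREAM_PAIRS = 15


@dataclass
class GroundTruth:
    """Planted structure behind one synthetic study."""

    gene_modules: dict[str, str] = field(default_factory=dict)
    gene_loadings: dict[str, float] = field(default_factory=dict)
    protein_families: dict[str, int | None] = field(default_factory=dict)
    positive_pairs: list[tuple[str, str]] = field(default_factory=list)
    module_terms: dict[str, list[str]] = field(default_factory=dict)
    true_tree: str | None = None

    def interacts(self, a: str, b: str) -> bool:
        """True interaction: both proteins belong to the same family."""
        fa = self.protein_families.get(a)
        fb = self.protein_families.get(b)
        return fa is not None and fa == fb and a != b


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# expression


def generate_expression(config: SimulationConfig) -> tuple[ExpressionData, GroundTruth]:
    """Plant latent-factor modules with controllable trait correlation.

    Module ``m`` has a latent sample profile correlating with the binary
    trait at roughly ``trait_assoc[m]``; gene ``i`` of the module is
    ``a_i * profile_m`` plus Gaussian noise with sd ``noise_sd``, with
    loadings ``a_i`` uniform on [0.5, 1]. Background genes are pure noise.
    """
    config.validate()
    if sum(config.module_sizes) == 0:
        raise ValueError("empty design: module sizes sum to 0")
    if config.n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = _rng(config.seed, _STREAM_EXPR)
    m = config.n_samples
    trait = np.zeros(m, dtype=int)
    trait[m // 2 :] = 1
    t_std = (trait - trait.mean()) / trait.std(ddof=0)

    columns: list[str] = []
    data: list[np.ndarray] = []
    truth = GroundTruth()
    gene_counter = 0
    for mod_idx, (size, rho) in enumerate(zip(config.module_sizes, config.trait_assoc)):
        latent = rho * t_std + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=m)
        module_id = f"M{mod_idx + 1}"
        loadings = rng.uniform(0.5, 1.0, size=size)
        noise = rng.normal(scale=1.0, size=(m, size))
        block = loadings[None, :] * latent[:, None] + config.noise_sd * noise
        for j in range(size):
            gene_counter += 1
            gid = f"G{gene_counter:04d}"
            columns.append(gid)
            truth.gene_modules[gid] = module_id
            truth.gene_loadings[gid] = float(loadings[j])
        data.append(block)
    if config.n_background_genes:
        block = rng.normal(size=(m, config.n_background_genes))
        for _ in range(config.n_background_genes):
            gene_counter += 1
            gid = f"G{gene_counter:04d}"
            columns.append(gid)
            truth.gene_modules[gid] = "background"
            truth.gene_loadings[gid] = 0.0
        data.append(block)
    values = pd.DataFrame(
        np.hstack(data),
        index=[f"S{i + 1:02d}" for i in range(m)],
        columns=columns,
    )
    trait_s = pd.Series(trait, index=values.index, name="trait")
    return ExpressionData(values=values, trait=trait_s), truth


# ---------------------------------------------------------------------------
# protein corpus


@dataclass
class FamilyProfile:
    pool_a: np.ndarray  # residue probabilities, length 20
    pool_b: np.ndarray
    template: np.ndarray  # periodic 0/1 segment pattern


def family_profiles(config: SimulationConfig) -> list[FamilyProfile]:
    """Family composition profiles, a pure function of (seed, n_families).

    Each family is built around one of the seven physicochemical property
    axes (order shuffled by the seed): pool A holds the two still-unused
    residues with the highest value on that axis, pool B the two lowest,
    so every family's two pools have a strong, family-specific property
    contrast and different families use disjoint residues. The pools are
    arranged in a family-specific periodic block template whose blocks are
    longer than the encoder's default lag window, so every lag carries
    template signal. ``signal_strength`` linearly mixes the pools with the
    uniform composition.
    """
    from .properties import standardized_property_matrix

    rng = _rng(config.seed, _STREAM_PROFILES)
    n_fam = config.n_families
    prop = standardized_property_matrix()
    n_axes = prop.shape[0]
    axes = [int(a) for a in rng.permutation(n_axes)]
    while len(axes) < n_fam:
        axes += [int(a) for a in rng.permutation(n_axes)]
    uniform = np.full(20, 0.05)
    s = config.signal_strength
    used: set[int] = set()
    profiles = []
    for f in range(n_fam):
        if len(used) > 20 - 4:
            used.clear()  # more families than disjoint pools; reuse residues
        order = [i for i in np.argsort(prop[axes[f]]) if i not in used]
        pool_b, pool_a = order[:2], order[-2:]
        used.update(pool_a)
        used.update(pool_b)
        pa = np.zeros(20)
        pa[pool_a] = 0.5
        pb = np.zeros(20)
        pb[pool_b] = 0.5
        pa = s * pa + (1 - s) * uniform
        pb = s * pb + (1 - s) * uniform
        template: list[int] = []
        for _ in range(2):
            template += [0] * int(rng.integers(35, 65))
            template += [1] * int(rng.integers(35, 65))
        profiles.append(
            FamilyProfile(pa / pa.sum(), pb / pb.sum(), np.array(template))
        )
    return profiles


def _family_sequence(
    rng: np.random.Generator, profile: FamilyProfile, length: int
) -> str:
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    t = np.resize(profile.template, length)
    seq = np.empty(length, dtype="<U1")
    for pool_id, pool in ((0, profile.pool_a), (1, profile.pool_b)):
        mask = t == pool_id
        seq[mask] = rng.choice(aa, size=int(mask.sum()), p=pool)
    return "".join(seq)


def generate_ppi_corpus(
    config: SimulationConfig,
    groups: list[list[str]] | None = None,
    background_ids: list[str] | None = None,
    stream: int = 0,
) -> tuple[dict[str, ProteinRecord], list[tuple[str, str]], GroundTruth]:
    """Generate proteins, a positive pair list, and localizations.

    Without ``groups``, the corpus contains ``n_proteins`` proteins of
    which a ``family_fraction`` share is split evenly over the interaction
    families (ids ``P0001`` ...), the rest being background; the returned
    positive list samples ``n_positive_pairs`` distinct same-family pairs.
    With ``groups``, each listed id group is one family (used by the
    pipeline to tie proteins to module genes) and the positive list is
    every within-group pair.

    Family members share one compartment; background proteins draw one or
    two compartments at random, so every positive pair co-localizes.
    """
    config.validate()
    profiles = family_profiles(config)
    rng = _rng(config.seed, _STREAM_SEQS + 10 * stream)
    pair_rng = _rng(config.seed, _STREAM_PAIRS + 10 * stream)
    lo, hi = config.protein_length_range
    truth = GroundTruth()
    n_fam = config.n_families

    if groups is None:
        if config.n_positive_pairs > config.n_proteins**2:
            raise ValueError("n_positive_pairs exceeds the number of possible pairs")
        per_fam = int(config.n_proteins * config.family_fraction / max(1, n_fam))
        counter = 0
        groups = []
        for _ in range(n_fam):
            ids = [f"P{counter + i + 1:04d}" for i in range(per_fam)]
            counter += per_fam
            groups.append(ids)
        background_ids = [
            f"P{counter + i + 1:04d}" for i in range(config.n_proteins - counter)
        ]
        sample_positives = config.n_positive_pairs
    else:
        background_ids = list(background_ids or [])
        sample_positives = None

    compartments = [f"C{i + 1}" for i in range(max(1, config.n_compartments))]
    proteins: dict[str, ProteinRecord] = {}
    for f, ids in enumerate(groups):
        profile = profiles[f % max(1, len(profiles))]
        comp = frozenset({compartments[f % len(compartments)]})
        for pid in ids:
            length = int(rng.integers(lo, hi + 1))
            seq = _family_sequence(rng, profile, length)
            proteins[pid] = ProteinRecord(id=pid, sequence=seq, localizations=comp)
            truth.protein_families[pid] = f
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    for pid in background_ids:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=length))
        n_comp = int(rng.integers(1, 3))
        comp = frozenset(
            rng.choice(compartments, size=min(n_comp, len(compartments)), replace=False)
        )
        proteins[pid] = ProteinRecord(id=pid, sequence=seq, localizations=comp)
        truth.protein_families[pid] = None

    same_family = [
        tuple(sorted(p))
        for ids in groups
        for p in combinations(ids, 2)
    ]
    if sample_positives is None:
        positives = same_family
    else:
        if sample_positives > len(same_family):
            raise ValueError(
                f"cannot plant {sample_positives} positive pairs; only "
                f"{len(same_family)} same-family pairs exist"
            )
        idx = pair_rng.choice(len(same_family), size=sample_positives, replace=False)
        positives = [same_family[i] for i in sorted(idx)]
    truth.positive_pairs = positives
    return proteins, positives, truth


# ---------------------------------------------------------------------------
# annotations


def generate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, set[str]]:
    """Annotate genes with terms, planting one enriched term per module.

    The first ``len(modules)`` terms draw their genes with weight
    ``enrichment_odds`` for the corresponding module's genes and weight 1
    elsewhere (``math.inf`` restricts the term to the module); remaining
    terms sample uniformly. Fills ``truth.module_terms``.
    """
    if not truth.gene_modules:
        raise ValueError("ground-truth gene partition required")
    if config.n_go_terms == 0:
        warnings.warn("n_go_terms is 0; returning an empty annotation table", stacklevel=2)
        return {}
    rng = _rng(config.seed, _STREAM_ANNOT)
    genes = np.array(sorted(truth.gene_modules))
    modules = sorted({m for m in truth.gene_modules.values() if m != "background"})
    lo, hi = config.term_size_range
    annotations: dict[str, set[str]] = {}
    term_idx = 0
    for module in modules:
        if term_idx >= config.n_go_terms:
            break
        term_idx += 1
        term = f"T{term_idx:03d}"
        size = int(rng.integers(lo, hi + 1))
        in_module = np.array([truth.gene_modules[g] == module for g in genes])
        if math.isinf(config.enrichment_odds):
            pool = genes[in_module]
            chosen = rng.choice(pool, size=min(size, len(pool)), replace=False)
        else:
            w = np.where(in_module, config.enrichment_odds, 1.0)
            chosen = rng.choice(
                genes, size=min(size, len(genes)), replace=False, p=w / w.sum()
            )
        annotations[term] = set(chosen.tolist())
        truth.module_terms.setdefault(module, []).append(term)
    while term_idx < config.n_go_terms:
        term_idx += 1
        term = f"T{term_idx:03d}"
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(genes, size=min(size, len(genes)), replace=False)
        annotations[term] = set(chosen.tolist())
    return annotations


# ---------------------------------------------------------------------------
# sequence families along a tree


def default_true_tree(n_taxa: int) -> str:
    """Two well-separated balanced clades with short within-clade branches."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for a two-clade tree")
    names = [f"T{i + 1}" for i in range(n_taxa)]

    def clade(taxa: list[str], branch: float) -> str:
        if len(taxa) == 1:
            return taxa[0]
        half = len(taxa) // 2
        return (
            f"({clade(taxa[:half], branch)}:{branch},"
            f"{clade(taxa[half:], branch)}:{branch})"
        )

    half = n_taxa // 2
    return f"({clade(names[:half], 0.04)}:0.3,{clade(names[half:], 0.04)}:0.3);"


def simulate_family(
    tree: str,
    root_seq_length: int,
    subst_rate: float,
    seed: int,
    alphabet: str = AMINO_ACIDS,
) -> dict[str, str]:
    """Evolve i.i.d. substitutions along a Newick tree.

    Each site on a branch of length ``b`` receives a Poisson(rate * b)
    number of substitutions, each to a uniformly chosen different residue.
    Returns leaf sequences keyed by taxon name in stable leaf order.
    """
    if subst_rate < 0:
        raise ValueError("substitution rate must be non-negative")
    try:
        parsed = Phylo.read(StringIO(tree), "newick")
    except Exception as exc:  # Bio raises bare exceptions on bad tokens
        raise ValueError(f"malformed Newick near {exc!s}: {tree[:80]!r}") from exc
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(31,))
    )
    letters = np.frombuffer(alphabet.encode(), dtype="S1").astype("U1")
    n_letters = len(letters)
    root_seq = rng.integers(0, n_letters, size=root_seq_length)

    leaves: dict[str, str] = {}

    def evolve(seq: np.ndarray, clade) -> None:
        bl = clade.branch_length or 0.0
        seq = seq.copy()
        if bl > 0 and subst_rate > 0:
            hits = rng.poisson(subst_rate * bl, size=len(seq))
            for pos in np.nonzero(hits)[0]:
                for _ in range(hits[pos]):
                    shift = rng.integers(1, n_letters)
                    seq[pos] = (seq[pos] + shift) % n_letters
        if clade.is_terminal():
            leaves[clade.name] = "".join(letters[seq])
        else:
            for child in clade.clades:
                evolve(seq, child)

    root = parsed.root
    if root.branch_length:
        evolve(root_seq, root)
    else:
        for child in root.clades:
            evolve(root_seq, child)
        if root.is_terminal():
            leaves[root.name] = "".join(letters[root_seq])
    return leaves
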