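"""Synthetic compound libraries with controlled scaffold structure.

The generator builds a library by decorating ring-system templates with small
inert substituents, so that the Bemis-Murcko scaffold of every product is the
template it came from by construction.  Scaffold sizes follow a Zipf-weight
largest-remainder allocation (deterministic, not sampled), from uniform
(``scaffold_concentration = 0``) to strongly dominated by the first scaffold.

Each scaffold carries a base activity profile drawn once per scaffold
(Bernoulli ``base_profile_density`` per target); each compound's profile is
the base profile with independent per-bit flips at ``noise_rate``.  Profile
similarity between compounds is therefore statistically coupled to scaffold
membership, with a closed-form expectation available for testing
(:func:`expected_profile_similarity`).

Everything is a pure function of the seed: one global seed is split into
independent structure and profile streams.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.error")  # sanitise failures are handled, not reported

from .errors import CapacityError, ParameterError
from .panel import generic_panel
from .types import CompoundLibrary, CompoundRecord

#: Ring-system templates; each is its own Bemis-Murcko scaffold.
RING_TEMPLATES: Tuple[str, ...] = (
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1cnccn1",            # pyrazine
    "c1ccoc1",             # furan
    "c1ccsc1",             # thiophene
    "c1cc[nH]c1",          # pyrrole
    "c1c[nH]cn1",          # imidazole
    "c1cocn1",             # oxazole
    "c1cscn1",             # thiazole
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2occc2c1",       # benzofuran
    "c1ccc2sccc2c1",       # benzothiophene
    "C1CCCCC1",            # cyclohexane
    "C1CCCC1",             # cyclopentane
    "C1CCNCC1",            # piperidine
    "C1COCCN1",            # morpholine
    "C1CCOCC1",            # tetrahydropyran
    "C1CCNC1",             # pyrrolidine
    "O=c1ccoc2ccccc12",    # chromen-4-one
    "O=c1ccc2ccccc2o1",    # coumarin
    "c1ccc(-c2ccccc2)cc1", # biphenyl
    "c1ccc2c(c1)CCC2",     # indane
    "c1ccc2c(c1)CCCC2",    # tetralin
    "C1C2CC3CC1CC(C2)C3",  # adamantane
    "C1CCCCCC1",           # cycloheptane
)

#: Substituents small enough to never perturb the parent scaffold:
#: methyl, hydroxyl, fluoro, methoxy (as atom chains grown off a ring carbon).
_SUBSTITUENTS: Tuple[Tuple[int, ...], ...] = (
    (6,),       # -CH3
    (8,),       # -OH
    (9,),       # -F
    (8, 6),     # -OCH3
)

_LINKERS = ("", "C", "CC", "CCC")


@dataclass
class SyntheticSpec:
    """Parameters of the generative model.

    Defaults describe a mid-diversity library: roughly two compounds per
    scaffold, moderately concentrated scaffold sizes, sparse profiles
    (about 1 in 10 targets active per scaffold) and 5% per-bit reporting
    noise.
    """

    n_compounds: int
    n_scaffolds: Optional[int] = None
    scaffold_concentration: float = 1.0
    n_targets: int = 46
    base_profile_density: float = 0.1
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ParameterError("n_compounds must be >= 1")
        if self.n_scaffolds is None:
            self.n_scaffolds = max(1, self.n_compounds // 2)
        if not 1 <= self.n_scaffolds <= self.n_compounds:
            raise ParameterError("need 1 <= n_scaffolds <= n_compounds")
        if self.n_targets < 1:
            raise ParameterError("n_targets must be >= 1")
        for p, label in (
            (self.base_profile_density, "base_profile_density"),
            (self.noise_rate, "noise_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{label} must be in [0, 1]")
        if self.scaffold_concentration < 0:
            raise ParameterError("scaffold_concentration must be >= 0")


def _canonical(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


def _is_self_scaffold(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return scaffold is not None and Chem.MolToSmiles(scaffold) == Chem.MolToSmiles(mol)


def _free_carbon(mol, atom_range) -> Optional[int]:
    for idx in atom_range:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() >= 1:
            return idx
    return None


def _link_templates(smiles_a: str, smiles_b: str, linker: str) -> Optional[str]:
    """Join two ring templates with a saturated linker; None on failure."""
    a = Chem.MolFromSmiles(smiles_a)
    b = Chem.MolFromSmiles(smiles_b)
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    na = a.GetNumAtoms()
    ai = _free_carbon(combo, range(na))
    bi = _free_carbon(combo, range(na, na + b.GetNumAtoms()))
    if ai is None or bi is None:
        return None
    prev = ai
    for _ in linker:
        new = combo.AddAtom(Chem.Atom(6))
        combo.AddBond(prev, new, Chem.BondType.SINGLE)
        prev = new
    combo.AddBond(prev, bi, Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(combo)
    except Exception:
        return None
    return Chem.MolToSmiles(combo)


def scaffold_templates(n: int) -> List[str]:
    """Deterministic list of ``n`` distinct self-scaffold templates.

    The fixed ring-system set is extended with linked two-ring variants
    (single bond, then -CH2-, -CH2CH2-, -CH2CH2CH2- linkers, in a fixed
    enumeration order) until ``n`` templates are available.
    """
    base = []
    seen = set()
    for t in RING_TEMPLATES:
        can = _canonical(t)
        if can not in seen and _is_self_scaffold(can):
            base.append(can)
            seen.add(can)
    templates = list(base)
    if len(templates) >= n:
        return templates[:n]
    for linker in _LINKERS:
        for i in range(len(base)):
            for j in range(i, len(base)):
                cand = _link_templates(base[i], base[j], linker)
                if cand is None or cand in seen or not _is_self_scaffold(cand):
                    continue
                templates.append(cand)
                seen.add(cand)
                if len(templates) >= n:
                    return templates
    raise CapacityError(
        f"requested {n} distinct scaffolds; only {len(templates)} available"
    )


def allocate_scaffold_counts(
    n_compounds: int, n_scaffolds: int, concentration: float
) -> np.ndarray:
    """Largest-remainder allocation of compounds to scaffolds by Zipf weights.

    Weight of scaffold k (1-based) is ``k ** -concentration``; 0 gives a
    uniform split.  Every scaffold receives at least one compound; the
    remaining ``n_compounds - n_scaffolds`` are apportioned by quota with
    ties broken toward the lower scaffold index.  Deterministic.
    """
    if not 1 <= n_scaffolds <= n_compounds:
        raise ParameterError("need 1 <= n_scaffolds <= n_compounds")
    counts = np.ones(n_scaffolds, dtype=int)
    rest = n_compounds - n_scaffolds
    if rest == 0:
        return counts
    weights = np.arange(1, n_scaffolds + 1, dtype=float) ** (-concentration)
    quota = rest * weights / weights.sum()
    floors = np.floor(quota).astype(int)
    counts += floors
    remainder = rest - int(floors.sum())
    if remainder:
        frac = quota - floors
        order = np.lexsort((np.arange(n_scaffolds), -frac))
        counts[order[:remainder]] += 1
    return counts


def _decorate(template: str, rng: np.random.Generator, max_substituents: int = 3) -> str:
    """Attach 0..max random inert substituents to ring carbons bearing an H.

    The product's Bemis-Murcko scaffold is verified to equal the template;
    on a (rare) verification failure the bare template is returned.
    """
    mol = Chem.MolFromSmiles(template)
    n_sub = int(rng.integers(0, max_substituents + 1))
    if n_sub == 0:
        return template
    for _ in range(10):  # retries; substitution can occasionally fail to sanitize
        rw = Chem.RWMol(Chem.MolFromSmiles(template))
        candidates = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 6 and a.IsInRing() and a.GetTotalNumHs() >= 1
        ]
        for _ in range(min(n_sub, len(candidates))):
            # each anchor is used at most once, so one implicit H always remains
            anchor = candidates.pop(int(rng.integers(len(candidates))))
            chain = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
            prev = int(anchor)
            for z in chain:
                new = rw.AddAtom(Chem.Atom(z))
                rw.AddBond(prev, new, Chem.BondType.SINGLE)
                prev = new
        try:
            Chem.SanitizeMol(rw)
        except Exception:
            continue
        smiles = Chem.MolToSmiles(rw)
        if MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles) == template:
            return smiles
    return template


def generate_with_assignments(
    spec: SyntheticSpec,
) -> Tuple[CompoundLibrary, np.ndarray, List[str]]:
    """Generate a library; also return per-compound scaffold indices and the
    template SMILES list (in allocation order)."""
    ss = np.random.SeedSequence(spec.seed)
    struct_ss, profile_ss = ss.spawn(2)
    struct_rng = np.random.default_rng(struct_ss)
    profile_rng = np.random.default_rng(profile_ss)

    templates = scaffold_templates(spec.n_scaffolds)
    counts = allocate_scaffold_counts(
        spec.n_compounds, spec.n_scaffolds, spec.scaffold_concentration
    )
    base_profiles = (
        profile_rng.random((spec.n_scaffolds, spec.n_targets))
        < spec.base_profile_density
    ).astype(np.uint8)
    flips = (
        profile_rng.random((spec.n_compounds, spec.n_targets)) < spec.noise_rate
    ).astype(np.uint8)

    panel = generic_panel(spec.n_targets)
    n_general = len(panel.general_families)
    records: List[CompoundRecord] = []
    assignments = np.empty(spec.n_compounds, dtype=int)
    cid = 0
    for k, (template, count) in enumerate(zip(templates, counts)):
        for _ in range(int(count)):
            smiles = _decorate(template, struct_rng)
            profile = base_profiles[k] ^ flips[cid]
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=f"SYN-{cid:04d}",
                    smiles=smiles,
                    specific_profile=profile,
                    general_flags=np.zeros(n_general, dtype=np.uint8),
                    food_sources=["synthetic"],
                )
            )
            assignments[cid] = k
            cid += 1
    library = CompoundLibrary(
        records=records, panel=panel, provenance=f"synthetic(seed={spec.seed})"
    )
    return library, assignments, templates


def generate_library(spec: SyntheticSpec) -> CompoundLibrary:
    """Generate a synthetic :class:`CompoundLibrary`; pure function of the seed."""
    return generate_with_assignments(spec)[0]


def expected_profile_similarity(spec: SyntheticSpec, same_scaffold: bool) -> float:
    """Exact expected Jaccard similarity of two compound profiles.

    The expectation is over the generative model (shared or independent base
    profiles, then independent per-bit flips), *conditional on the pair being
    defined* (at least one bit set in the union); undefined all-zero pairs
    carry the flagged 0.0 convention and are excluded, matching how empirical
    means are taken.  Computed by exact enumeration over the per-bit joint
    outcomes and the (intersection, union) counting distribution.
    """
    p = spec.base_profile_density
    e = spec.noise_rate
    n = spec.n_targets
    if same_scaffold:
        p11 = p * (1 - e) ** 2 + (1 - p) * e**2
        p_diff = 2 * e * (1 - e)  # P(x=1,y=0) + P(x=0,y=1), independent of p
    else:
        q = p * (1 - e) + (1 - p) * e
        p11 = q * q
        p_diff = 2 * q * (1 - q)
    p00 = 1.0 - p11 - p_diff
    if p11 + p_diff == 0.0:
        raise ParameterError("profiles are all-zero almost surely; similarity undefined")
    total = 0.0
    p_defined = 1.0 - p00**n
    for u in range(1, n + 1):
        c_nu = math.comb(n, u)
        for a in range(0, u + 1):
            prob = (
                c_nu
                * math.comb(u, a)
                * p11**a
                * p_diff ** (u - a)
                * p00 ** (n - u)
            )
            total += (a / u) * prob
    return min(1.0, total / p_defined)
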