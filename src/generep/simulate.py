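"""Synthetic data with known ground truth for every pipeline stage.

Generates gene universes, role-tagged catalogs, condition sets with planted
enrichment (specified as a conditional rate: the expected fraction of
condition genes falling inside a chosen catalog set), paired signed
differential sets with controlled direction concordance, and impedance growth
curves with a known drug effect.  Everything is driven by one
``numpy.random.Generator``; a fixed seed gives byte-identical outputs, and
each generator returns a machine-readable ground-truth record alongside the
data so planted quantities can be recomputed independently of the pipeline.

Default dimensions mirror the reference study design this package was built
around: a ~31.5k-symbol genome universe, 48 pathway-target and 52 TF-target
sets, and condition sets of a few hundred genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geneset import Catalog, GeneSet, Universe

__all__ = [
    "SyntheticSpec",
    "PlantedEnrichment",
    "generate_universe",
    "generate_catalog",
    "plant_condition_set",
    "planted_crosstab_fixture",
    "generate_paired_signed_sets",
    "generate_growth_curves",
    "write_truth_json",
]


@dataclass(frozen=True)
class PlantedEnrichment:
    """One planted signal: the condition set hits ``catalog_set`` at ``conditional_rate``."""

    catalog_set: str
    conditional_rate: float

    def __post_init__(self) -> None:
        if not (0.0 < self.conditional_rate < 1.0):
            raise ValueError("conditional_rate must lie strictly in (0, 1)")


@dataclass
class SyntheticSpec:
    """Generative parameters for a full synthetic study.

    Defaults emulate the reference design: genome universe of 31524 symbols,
    48 pathway and 52 TF target catalogs with sizes tuned so the catalog
    union covers roughly 30-75% of the universe, and condition sets of a few
    hundred genes (447 for the pan-human context, 129 for the cell-line
    context).
    """

    universe_size: int = 31524
    n_pathway_sets: int = 48
    n_tf_sets: int = 52
    set_size_range: tuple[int, int] = (30, 1200)
    condition_sizes: tuple[int, ...] = (447, 129)
    planted: list[PlantedEnrichment] = field(default_factory=list)
    concordance: float = 213 / 364
    core_size: int = 364
    fc_sigma: float = 0.5  # log-normal spread of fold-change magnitudes
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_universe(spec: SyntheticSpec, name: str = "synthetic_genome") -> Universe:
    """Deterministic synthetic universe G000001..G<N>."""
    if spec.universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    return Universe(genes=frozenset(_symbols(spec.universe_size)), name=name)


def generate_catalog(
    spec: SyntheticSpec,
    role: str,
    universe: Universe,
    rng: np.random.Generator | None = None,
    n_sets: int | None = None,
    prefix: str | None = None,
) -> Catalog:
    """Draw a catalog of sets, each uniform without replacement from the universe.

    Set sizes are uniform in ``set_size_range``; overlap between sets arises
    by chance only (real pathway/TF target catalogs overlap more — a stated
    fidelity limitation of the generator).
    """
    rng = rng if rng is not None else spec.rng()
    if n_sets is None:
        n_sets = spec.n_pathway_sets if role == "pathway_targets" else spec.n_tf_sets
    if prefix is None:
        prefix = {"pathway_targets": "PW", "tf_targets": "TF"}.get(role, "SET")
    lo, hi = spec.set_size_range
    if hi > len(universe):
        raise ValueError(f"set size bound {hi} exceeds universe size {len(universe)}")
    pool = np.array(sorted(universe.genes))
    catalog = Catalog(role=role, universe=universe)
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(pool, size=size, replace=False)
        catalog.add(
            GeneSet(
                name=f"{prefix}{i:03d}",
                genes=frozenset(str(g) for g in members),
                description=f"synthetic {role} set",
                provenance="simulate.generate_catalog",
            )
        )
    return catalog


def plant_condition_set(
    spec: SyntheticSpec,
    catalog: Catalog,
    universe: Universe,
    size: int,
    planted: list[PlantedEnrichment] | None = None,
    rng: np.random.Generator | None = None,
    name: str = "condition",
) -> tuple[GeneSet, dict]:
    """Draw a condition set with planted conditional rates inside chosen catalog sets.

    For each planted entry, the number of condition genes falling inside the
    target catalog set is Binomial(size, rate) (so the conditional rate holds
    in expectation with binomial spread); those genes are drawn from the
    target set, the remainder uniformly from outside all planted sets.  With
    no planted entries the draw is uniform over the universe.

    Returns (condition set, ground-truth record with specified and realized
    rates).
    """
    rng = rng if rng is not None else spec.rng()
    planted = list(planted) if planted is not None else list(spec.planted)
    for p in planted:
        if p.catalog_set not in catalog.sets:
            raise ValueError(f"planted set {p.catalog_set!r} not in catalog")
    if size > len(universe):
        raise ValueError("condition size exceeds universe")

    chosen: set[str] = set()
    truth_planted = []
    forbidden: set[str] = set()
    for p in planted:
        forbidden |= catalog.sets[p.catalog_set].genes & universe.genes
    for p in planted:
        target_pool = sorted((catalog.sets[p.catalog_set].genes & universe.genes) - chosen)
        k = int(rng.binomial(size, p.conditional_rate))
        if k > len(target_pool):
            raise ValueError(
                f"infeasible planting: need {k} genes from {p.catalog_set!r} "
                f"but only {len(target_pool)} are available"
            )
        picked = rng.choice(np.array(target_pool), size=k, replace=False) if k else np.array([])
        chosen |= {str(g) for g in picked}
        truth_planted.append(
            {"catalog_set": p.catalog_set, "specified_rate": p.conditional_rate, "planted_k": k}
        )
    n_rest = size - len(chosen)
    if n_rest < 0:
        raise ValueError("infeasible planting: joint overlaps exceed condition size")
    outside = sorted(universe.genes - forbidden - chosen)
    if n_rest > len(outside):
        raise ValueError("infeasible planting: not enough genes outside planted sets")
    rest = rng.choice(np.array(outside), size=n_rest, replace=False) if n_rest else np.array([])
    chosen |= {str(g) for g in rest}

    gs = GeneSet(
        name=name,
        genes=frozenset(chosen),
        description="synthetic condition set",
        provenance="simulate.plant_condition_set",
    )
    for rec in truth_planted:
        members = catalog.sets[rec["catalog_set"]].genes
        rec["realized_rate"] = len(gs.genes & members) / size
    truth = {"name": name, "size": size, "universe": universe.name, "planted": truth_planted}
    return gs, truth


def generate_paired_signed_sets(
    spec: SyntheticSpec,
    universe: Universe,
    rng: np.random.Generator | None = None,
    core_size: int | None = None,
    concordance: float | None = None,
    extra_a: int = 0,
    extra_b: int = 0,
    apply_threshold: bool = True,
    fc_threshold: float = 1.4,
) -> tuple[GeneSet, GeneSet, dict]:
    """Two signed sets sharing a core with controlled direction concordance.

    The shared core has ``core_size`` genes of which exactly
    round(concordance * core_size) agree in sign between the two sets;
    ``extra_a``/``extra_b`` genes are private to each side.  Fold-change
    magnitudes are log-normal; with ``apply_threshold`` they are guaranteed to
    exceed the symmetric threshold, emulating pre-filtered differential lists.
    """
    rng = rng if rng is not None else spec.rng()
    core_size = core_size if core_size is not None else spec.core_size
    concordance = concordance if concordance is not None else spec.concordance
    if not (0.0 <= concordance <= 1.0):
        raise ValueError("concordance must lie in [0, 1]")
    total = core_size + extra_a + extra_b
    pool = rng.choice(np.array(sorted(universe.genes)), size=total, replace=False)
    core = [str(g) for g in pool[:core_size]]
    priv_a = [str(g) for g in pool[core_size : core_size + extra_a]]
    priv_b = [str(g) for g in pool[core_size + extra_a :]]

    n_concordant = round(concordance * core_size)
    signs_a = {g: int(s) for g, s in zip(core, rng.choice([-1, 1], size=core_size))}
    signs_b = dict(signs_a)
    for g in core[n_concordant:]:
        signs_b[g] = -signs_a[g]
    for g in priv_a:
        signs_a[g] = int(rng.choice([-1, 1]))
    for g in priv_b:
        signs_b[g] = int(rng.choice([-1, 1]))

    def _fc(sign: int) -> float:
        # magnitude > base always, so sign and fold change stay consistent
        base = fc_threshold if apply_threshold else 1.0
        magnitude = base * float(np.exp(abs(rng.normal(0.0, spec.fc_sigma))) + 1e-9)
        return magnitude if sign > 0 else 1.0 / magnitude

    def _build(name: str, signs: dict[str, int]) -> GeneSet:
        fc = {g: _fc(s) for g, s in signs.items()}
        return GeneSet(
            name=name,
            genes=frozenset(signs),
            direction=signs,
            fold_change=fc,
            description="synthetic signed differential set",
            provenance="simulate.generate_paired_signed_sets",
        )

    a = _build("signed_a", signs_a)
    b = _build("signed_b", signs_b)
    truth = {
        "core_size": core_size,
        "concordance": concordance,
        "n_concordant": n_concordant,
        "n_discordant": core_size - n_concordant,
        "extra_a": extra_a,
        "extra_b": extra_b,
        "core_genes": sorted(core),
    }
    return a, b, truth


def planted_crosstab_fixture(
    universe: Universe,
    rng: np.random.Generator,
    n_sets: int = 48,
    n_enriched: int = 27,
    set_size: int = 600,
    condition_size: int = 447,
    enriched_rate: float = 0.5,
    role: str = "pathway_targets",
) -> tuple[Catalog, GeneSet, dict]:
    """Noiseless planted cross-tabulation: exact overlap counts, no sampling spread.

    The condition set is drawn uniformly; each of the first ``n_enriched``
    catalog sets is then constructed to contain exactly
    round(enriched_rate * condition_size) condition genes, while every null
    set contains exactly its null-expected count round(set_size *
    condition_size / N).  Enriched cells are therefore significant and null
    cells sit at the background rate — the planting limit in which the
    significant-cell count equals ``n_enriched`` exactly.
    """
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    N = len(universe)
    pool = np.array(sorted(universe.genes))
    cond_idx = rng.choice(N, size=condition_size, replace=False)
    cond_mask = np.zeros(N, dtype=bool)
    cond_mask[cond_idx] = True
    cond_genes = pool[cond_mask]
    other_genes = pool[~cond_mask]

    catalog = Catalog(role=role, universe=universe)
    k_enriched = round(enriched_rate * condition_size)
    k_null = round(set_size * condition_size / N)
    for i in range(1, n_sets + 1):
        k = k_enriched if i <= n_enriched else k_null
        inside = rng.choice(cond_genes, size=k, replace=False)
        outside = rng.choice(other_genes, size=set_size - k, replace=False)
        catalog.add(
            GeneSet(
                name=f"PW{i:03d}",
                genes=frozenset(str(g) for g in inside) | frozenset(str(g) for g in outside),
                description="synthetic planted set" if i <= n_enriched else "synthetic null set",
                provenance="simulate.planted_crosstab_fixture",
            )
        )
    condition = GeneSet(
        name="condition",
        genes=frozenset(str(g) for g in cond_genes),
        description="synthetic condition set",
        provenance="simulate.planted_crosstab_fixture",
    )
    truth = {
        "n_sets": n_sets,
        "n_enriched": n_enriched,
        "enriched_sets": [f"PW{i:03d}" for i in range(1, n_enriched + 1)],
        "k_enriched": k_enriched,
        "k_null": k_null,
        "condition_size": condition_size,
    }
    return catalog, condition, truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def generate_growth_curves(
    rng: np.random.Generator,
    doses: np.ndarray,
    ic50: float | tuple[float, float] = 1e-5,
    hill: float = 1.0,
    emax: float = 1.0,
    ci0: float = 0.15,
    rate: float = 0.25,
    capacity: float = 8.0,
    t_end: float = 72.0,
    dt: float = 1.0,
    t0: float = 24.0,
    noise_sigma: float = 0.0,
    replicates: int = 1,
) -> tuple[list, dict]:
    """Simulate RTCA traces: logistic growth with a post-treatment drug effect.

    The drug-free trace is logistic, L(t) = capacity / (1 + (capacity/ci0 - 1)
    e^(-rate t)).  From the treatment time t0 onward the trace is multiplied
    by the inhibition factor 1 - emax * d^hill / (d^hill + ic50^hill), so the
    normalized CI at any post-treatment time is an exact 4PL in dose.  ``ic50``
    may be a (start, end) pair for a log-linear drift over (t0, t_end).  Noise
    is multiplicative log-normal: ci * exp(sigma * eps).

    Returns (curves, truth record).  Imported lazily to avoid a module cycle:
    curves are :class:`generep.rtca.GrowthCurve`.
    """
    from .rtca import GrowthCurve

    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be nonnegative")
    for val, nm in ((hill, "hill"), (emax, "emax"), (ci0, "ci0"), (rate, "rate"), (capacity, "capacity")):
        if val <= 0 and nm != "emax":
            raise ValueError(f"{nm} must be positive")
    times = np.arange(0.0, t_end + dt / 2, dt)
    logistic = capacity / (1.0 + (capacity / ci0 - 1.0) * np.exp(-rate * times))

    drift = isinstance(ic50, (tuple, list))
    if drift:
        ic50_start, ic50_end = float(ic50[0]), float(ic50[1])
    else:
        ic50_start = ic50_end = float(ic50)

    def ic50_at(t: float) -> float:
        if not drift or t <= t0:
            return ic50_start
        frac = (t - t0) / (t_end - t0)
        return float(10 ** (np.log10(ic50_start) + frac * (np.log10(ic50_end) - np.log10(ic50_start))))

    curves = []
    for d_idx, d in enumerate(doses):
        for r in range(replicates):
            inhibition = np.ones_like(times)
            if d > 0:
                for i, t in enumerate(times):
                    if t > t0:
                        i50 = ic50_at(t)
                        inhibition[i] = 1.0 - emax * d**hill / (d**hill + i50**hill)
            ci = logistic * inhibition
            if noise_sigma > 0:
                ci = ci * np.exp(noise_sigma * rng.standard_normal(ci.shape))
            curves.append(
                GrowthCurve(
                    times=times,
                    ci=ci,
                    well=f"D{d_idx:02d}R{r}",
                    condition={"dose_M": float(d), "replicate": r},
                    t0=t0,
                )
            )
    truth = {
        "ic50_start": ic50_start,
        "ic50_end": ic50_end,
        "hill": hill,
        "emax": emax,
        "ci0": ci0,
        "rate": rate,
        "capacity": capacity,
        "t0": t0,
        "noise_sigma": noise_sigma,
        "doses": doses.tolist(),
        "replicates": replicates,
    }
    return curves, truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    """Persist a ground-truth record (sorted keys; byte-stable across runs)."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
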