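"""Synthetic longitudinal multi-segment gut microbiome + metabolome studies.

The generator emulates the design of a broiler-chicken developmental
cohort: ten birds sampled at eight days posthatch (1, 4, 7, 14, 21, 28,
35, 42) across four gut segments (duodenum, jejunum, ileum, cecum), with
bacterial and fungal communities profiled jointly with qPCR loads and a
time-course serum metabolome. Every downstream stage of the pipeline is
exercisable against the known ground truth it returns.

Planted structure:

* absolute loads follow a per-segment logistic curve (carrying capacity
  in copies/g, growth rate per day, inflection day) times lognormal
  noise, rising to a plateau by ~7 days posthatch;
* counts are Dirichlet-multinomial draws around segment-specific
  community-type centroids, with partial transmission mixing each
  segment's expected composition with its adjacent anterior segment;
* designated taxa follow colonization / disappearance / core occurrence
  patterns, enforced on detection after an absolute-abundance detection
  limit is applied;
* metabolites follow one of six trajectory templates (or stay flat), and
  a designated metabolite block is linearly coupled on the log scale to
  a designated microbe block to plant microbe–metabolite co-occurrence.

All randomness flows through a single seeded generator: the same seed
yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .tables import SEGMENT_ORDER, FeatureTable

DPH_GRID = (1, 4, 7, 14, 21, 28, 35, 42)

TRAJECTORY_TEMPLATES: dict[str, np.ndarray] = {
    # z-shaped mean profiles over the 8 sampling days
    "monotone-up": np.linspace(-1.2, 1.2, 8),
    "monotone-down": np.linspace(1.2, -1.2, 8),
    "step-up": np.array([-1.5, 0.55, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]),
    "step-down": np.array([1.5, -0.55, -0.6, -0.6, -0.6, -0.6, -0.6, -0.6]),
    "up-then-down": np.array([-1.0, 0.2, 1.1, 1.3, 0.8, 0.0, -0.8, -1.4]),
    "gradual-down": np.array([0.9, 0.9, 0.8, 0.5, 0.1, -0.4, -1.0, -1.8]),
}

SUPERCLASSES = (
    "Lipids and lipid-like molecules",
    "Organic acids and derivatives",
    "Benzenoids",
    "Organoheterocyclic compounds",
    "Organic oxygen compounds",
    "Nucleosides, nucleotides, and analogues",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class LogisticLoad:
    carrying_capacity: float  # copies/g at plateau
    growth_rate: float = 2.0  # per day
    inflection_day: float = 3.0

    def mean(self, day: float) -> float:
        return self.carrying_capacity / (
            1.0 + np.exp(-self.growth_rate * (day - self.inflection_day))
        )


@dataclass
class PatternSpec:
    """How many taxa per domain follow each planted occurrence pattern."""

    colonization: int = 15
    disappearance: int = 10
    core: int = 18

    @property
    def total(self) -> int:
        return self.colonization + self.disappearance + self.core


def _default_loads() -> dict:
    return {
        "bacteria": {
            "duodenum": LogisticLoad(1e8),
            "jejunum": LogisticLoad(3e8),
            "ileum": LogisticLoad(1e9),
            "cecum": LogisticLoad(1e10),
        },
        "fungi": {
            "duodenum": LogisticLoad(1e6),
            "jejunum": LogisticLoad(1e6),
            "ileum": LogisticLoad(3e6),
            "cecum": LogisticLoad(1e7),
        },
    }


def _default_transmission() -> dict:
    return {
        ("duodenum", "jejunum"): 0.3,
        ("jejunum", "ileum"): 0.3,
        ("ileum", "cecum"): 0.3,
    }


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated design: 10 birds x 4 segments x 8 days
    for two microbial domains, five bacterial and four fungal community
    types, ~1000 metabolites of which ~58% are time-associated across
    six trajectory shapes.
    """

    n_birds: int = 10
    segments: tuple = SEGMENT_ORDER
    timepoints: tuple = DPH_GRID
    n_taxa_bacteria: int = 100
    n_taxa_fungi: int = 50
    n_types_bacteria: int = 5
    n_types_fungi: int = 4
    load_curve_params: dict = field(default_factory=_default_loads)
    transmission: dict = field(default_factory=_default_transmission)
    pattern_spec: PatternSpec = field(default_factory=PatternSpec)
    n_metabolites: int = 1000
    cluster_trajectories: dict = field(
        default_factory=lambda: dict(TRAJECTORY_TEMPLATES)
    )
    # noise / nuisance parameters
    depth: int = 20000  # sequencing depth per sample
    concentration: float = 200.0  # Dirichlet overdispersion (higher = tighter)
    load_sigma_log10: float = 0.25
    pattern_noise: float = 0.005  # per-cell detection flip probability
    metabolite_noise_sd: float = 0.15  # log10 units
    metabolite_amplitude: float = 0.5  # log10 swing of trajectory templates
    flat_metabolite_fraction: float = 0.42
    unannotated_fraction: float = 0.10
    rare_metabolite_fraction: float = 0.05
    n_discriminative: int = 10
    coupling_strength: float = 0.9
    coupled_block_size: tuple = (8, 20)  # (microbes, metabolites)
    block_effect_log10: float = 1.0  # per-unit-activity swing of block microbes
    detection_limit: float = 1e3  # copies/g, lowest standard-curve point
    curve_slope: float = -3.3219
    curve_intercept: float = 38.0
    dilution_factor: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ConfigurationError("timepoints must be strictly increasing")
        if self.n_birds <= 0 or self.n_taxa_bacteria <= 0 or self.n_taxa_fungi <= 0:
            raise ConfigurationError("counts must be positive")
        for tau in self.transmission.values():
            if not 0 <= tau <= 1:
                raise ConfigurationError("transmission proportions must be in [0,1]")
        for n_taxa, dom in ((self.n_taxa_bacteria, "bacteria"), (self.n_taxa_fungi, "fungi")):
            if self.pattern_spec.total > n_taxa:
                raise ConfigurationError(
                    f"pattern_spec assigns {self.pattern_spec.total} taxa but "
                    f"{dom} has only {n_taxa}"
                )
        for name in self.cluster_trajectories:
            if name not in TRAJECTORY_TEMPLATES and len(
                self.cluster_trajectories[name]
            ) != len(self.timepoints):
                raise ConfigurationError(f"unknown trajectory template {name!r}")


@dataclass
class GroundTruth:
    """Planted labels for every synthetic entity."""

    loads: pd.DataFrame  # sample_id, domain, load (copies/g)
    community_type: dict  # domain -> Series sample_id -> type id
    source_proportions: pd.DataFrame  # source_segment, sink_segment, proportion
    occurrence: pd.DataFrame  # domain, taxon, category, onset_dph, offset_dph
    metabolite_cluster: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    discriminative_metabolites: set = field(default_factory=set)
    coupled_microbes: list = field(default_factory=list)
    coupled_metabolites: list = field(default_factory=list)
    coupled_segment: str = ""
    coupled_domain: str = ""
    block_signal: pd.DataFrame = field(default_factory=pd.DataFrame)  # bird x dph z
    annotated: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    metabolite_taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_tree(taxa: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random coalescent-style tree: repeatedly join two random lineages
    at exponentially spaced heights (ultrametric)."""
    items = [(name, 0.0) for name in taxa]
    height = 0.0
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        height += float(rng.exponential(0.5))
        (ni, hi), (nj, hj) = items[i], items[j]
        merged = f"({ni}:{height - hi:.6f},{nj}:{height - hj:.6f})"
        items = [items[k] for k in range(len(items)) if k not in (i, j)]
        items.append((merged, height))
    newick = items[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


def _lineages(taxa: list[str], domain: str, rng: np.random.Generator) -> pd.Series:
    root = "Bacteria" if domain == "bacteria" else "Fungi"
    vals = {}
    for t in taxa:
        ph, fa = rng.integers(1, 6), rng.integers(1, 11)
        vals[t] = (
            f"d__{root};p__P{ph};c__C{ph};o__O{fa};f__F{fa};g__{t}"
        )
    return pd.Series(vals)


def simulate_microbiome(config: SimConfig):
    """Generate the microbiome side of the study.

    Returns ``(tables, loads, trees, truth)`` where ``tables`` and
    ``trees`` are dicts keyed by domain ("bacteria", "fungi"), ``loads``
    is the qPCR measurement table (sample_id, domain, ct, sample_weight,
    dilution_factor) and ``truth`` the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    segments = list(config.segments)
    days = list(config.timepoints)
    birds = [f"B{b+1:02d}" for b in range(config.n_birds)]

    tables: dict[str, FeatureTable] = {}
    trees: dict[str, dendropy.Tree] = {}
    load_rows = []
    truth_loads = []
    truth_types: dict[str, pd.Series] = {}
    occ_rows = []
    block_signal = None
    coupled = {}

    domains = [
        ("bacteria", config.n_taxa_bacteria, config.n_types_bacteria),
        ("fungi", config.n_taxa_fungi, config.n_types_fungi),
    ]
    for domain, n_taxa, n_types in domains:
        taxa = [f"{'Bg' if domain == 'bacteria' else 'Fg'}{i+1:03d}" for i in range(n_taxa)]
        trees[domain] = simulate_tree(taxa, rng)
        lineage = _lineages(taxa, domain, rng)

        # sparse community-type centroids: each type occupies a subset of
        # the taxon pool, as real genus tables do
        centroids = rng.dirichlet(np.full(n_taxa, 0.3), size=n_types)
        for krow in range(n_types):
            off = rng.random(n_taxa) < 0.4
            centroids[krow, off] = 0.0
            centroids[krow] /= centroids[krow].sum()
        # planted pattern taxa (disjoint), boosted so detection is reliable
        spec = config.pattern_spec
        order = rng.permutation(n_taxa)
        col_idx = order[: spec.colonization]
        dis_idx = order[spec.colonization : spec.colonization + spec.disappearance]
        core_idx = order[spec.colonization + spec.disappearance : spec.total]
        planted = np.concatenate([col_idx, dis_idx, core_idx]).astype(int)
        centroids[:, planted] = np.maximum(centroids[:, planted], 0.004)
        centroids /= centroids.sum(axis=1, keepdims=True)

        onset = {int(i): days[int(rng.integers(1, len(days)))] for i in col_idx}
        offset = {int(i): days[int(rng.integers(1, len(days)))] for i in dis_idx}
        for i in col_idx:
            occ_rows.append(
                {"domain": domain, "taxon": taxa[int(i)], "category": "colonization",
                 "onset_dph": onset[int(i)], "offset_dph": None}
            )
        for i in dis_idx:
            occ_rows.append(
                {"domain": domain, "taxon": taxa[int(i)], "category": "disappearance",
                 "onset_dph": None, "offset_dph": offset[int(i)]}
            )
        for i in core_idx:
            occ_rows.append(
                {"domain": domain, "taxon": taxa[int(i)], "category": "core",
                 "onset_dph": None, "offset_dph": None}
            )

        # planted microbe-metabolite coupling: a latent per-(bird, day)
        # "block activity" jointly drives the block microbes' relative
        # abundance in the designated segment and (in the metabolome
        # generator) the coupled metabolites' intensities
        if domain == "bacteria":
            n_block = config.coupled_block_size[0]
            block_idx = core_idx[:n_block].astype(int)
            block_names = [taxa[int(i)] for i in block_idx]
            activity = {
                (bird, day): float(rng.normal())
                for bird in birds
                for day in days
            }
            coupled = {"microbes": block_names, "segment": "cecum",
                       "domain": "bacteria"}
            block_signal = pd.DataFrame(
                [{"bird": b, "dph": d, "z": z} for (b, d), z in activity.items()]
            )

        # segment-specific community-type preferences
        seg_type_probs = {}
        for si, seg in enumerate(segments):
            pvec = np.full(n_types, 0.25 / max(n_types - 1, 1))
            pvec[si % n_types] = 0.75
            seg_type_probs[seg] = pvec / pvec.sum()

        count_rows = {}
        meta_rows = {}
        type_labels = {}
        for bird in birds:
            for day in days:
                realized_by_seg = {}
                for si, seg in enumerate(segments):
                    ctype = int(rng.choice(n_types, p=seg_type_probs[seg]))
                    base = centroids[ctype]
                    sid = f"{bird}_{seg}_{day:02d}d_{domain[0]}"
                    alpha = base * config.concentration
                    own = rng.dirichlet(np.maximum(alpha, 1e-6))
                    # transmission: the realized anterior community seeds
                    # this segment, mixed at the configured proportion
                    if si > 0:
                        tau = config.transmission.get((segments[si - 1], seg), 0.0)
                        props = (1 - tau) * own + tau * realized_by_seg[segments[si - 1]]
                    else:
                        props = own
                    realized_by_seg[seg] = props
                    props = props.copy()
                    if domain == "bacteria" and seg == "cecum":
                        props[block_idx] *= 10.0 ** (
                            config.block_effect_log10 * activity[(bird, day)]
                        )
                        props /= props.sum()
                    # true absolute load for this sample
                    curve = config.load_curve_params[domain][seg]
                    load = curve.mean(day) * 10 ** rng.normal(0, config.load_sigma_log10)
                    # organisms below the absolute detection limit are absent;
                    # the remaining community fills the sequencing depth
                    below = props * load < config.detection_limit
                    if not below.all():
                        props[below] = 0.0
                    # planted occurrence patterns shape the community itself
                    absent_now = [i for i in col_idx if day < onset[int(i)]]
                    absent_now += [i for i in dis_idx if day >= offset[int(i)]]
                    present_now = [i for i in col_idx if day >= onset[int(i)]]
                    present_now += [i for i in dis_idx if day < offset[int(i)]]
                    present_now += list(core_idx)
                    props[absent_now] = 0.0
                    props[present_now] = np.maximum(
                        props[present_now], 5.0 / config.depth
                    )
                    props /= props.sum()
                    counts = rng.multinomial(config.depth, props).astype(float)
                    # guarantee detection of planted present taxa
                    counts[present_now] = np.maximum(counts[present_now], 1.0)
                    # mild detection noise at the margin: spurious single-copy
                    # detections and dropouts of near-threshold planted cells
                    if config.pattern_noise > 0:
                        flips = rng.random(len(planted)) < config.pattern_noise
                        for i, fl in zip(planted, flips):
                            if not fl:
                                continue
                            if counts[i] == 0:
                                counts[i] = 1.0
                            elif counts[i] <= 5:
                                counts[i] = 0.0
                    count_rows[sid] = counts
                    meta_rows[sid] = {
                        "bird": bird, "segment": seg, "dph": day, "domain": domain,
                    }
                    type_labels[sid] = f"T{ctype + 1}"
                    weight = float(np.clip(rng.normal(0.2, 0.02), 0.05, None))
                    copies_reaction = load * weight / config.dilution_factor
                    ct = config.curve_intercept + config.curve_slope * np.log10(
                        max(copies_reaction, 1e-12)
                    )
                    load_rows.append(
                        {
                            "sample_id": sid, "domain": domain, "ct": float(ct),
                            "sample_weight": weight,
                            "dilution_factor": config.dilution_factor,
                        }
                    )
                    truth_loads.append(
                        {"sample_id": sid, "domain": domain, "load": float(load)}
                    )

        data = pd.DataFrame.from_dict(count_rows, orient="index", columns=taxa)
        meta = pd.DataFrame.from_dict(meta_rows, orient="index")
        tables[domain] = FeatureTable(data, meta, lineage, "counts")
        truth_types[domain] = pd.Series(type_labels, name="community_type")

    src_rows = [
        {"source_segment": a, "sink_segment": b, "proportion": tau}
        for (a, b), tau in config.transmission.items()
    ]
    truth = GroundTruth(
        loads=pd.DataFrame(truth_loads),
        community_type=truth_types,
        source_proportions=pd.DataFrame(src_rows),
        occurrence=pd.DataFrame(occ_rows),
        coupled_microbes=coupled.get("microbes", []),
        coupled_segment=coupled.get("segment", ""),
        coupled_domain=coupled.get("domain", ""),
        block_signal=block_signal if block_signal is not None else pd.DataFrame(),
    )
    loads = pd.DataFrame(load_rows)
    return tables, loads, trees, truth


def simulate_metabolome(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Generate the serum metabolome (samples = bird x day).

    Returns the raw intensity table and fills in the metabolite fields
    of ``truth``: cluster labels, annotation flags, discriminative and
    coupled sets, and the chemical taxonomy (``truth.metabolite_taxonomy``).
    Trajectory templates are applied on the log10 scale with Gaussian
    noise; a designated block is linearly coupled to the planted
    microbe-block signal.
    """
    rng = np.random.default_rng(config.seed + 10_007)
    days = list(config.timepoints)
    birds = [f"B{b+1:02d}" for b in range(config.n_birds)]
    n = config.n_metabolites
    mets = [f"M{i+1:04d}" for i in range(n)]
    if n == 0:
        empty = pd.DataFrame(
            index=[f"{b}_{d:02d}d_serum" for b in birds for d in days], columns=[]
        )
        truth.metabolite_cluster = pd.Series(dtype=object)
        truth.metabolite_taxonomy = pd.DataFrame(
            columns=["superclass", "class", "subclass"]
        )
        return empty

    template_names = list(config.cluster_trajectories)
    n_flat = int(round(config.flat_metabolite_fraction * n))
    labels = np.array(
        ["flat"] * n_flat
        + [template_names[i % len(template_names)] for i in range(n - n_flat)]
    )
    rng.shuffle(labels)
    truth.metabolite_cluster = pd.Series(labels, index=mets, name="template")

    # chemical taxonomy: the monotone-up cluster is planted lipid-heavy
    superclass = []
    for lab in labels:
        if lab == "monotone-up":
            superclass.append(
                SUPERCLASSES[0] if rng.random() < 0.7
                else SUPERCLASSES[int(rng.integers(1, len(SUPERCLASSES)))]
            )
        else:
            superclass.append(SUPERCLASSES[int(rng.integers(0, len(SUPERCLASSES)))])
    annotated = rng.random(n) >= config.unannotated_fraction
    taxonomy = pd.DataFrame(
        {
            "superclass": np.where(annotated, superclass, "unknown"),
            "class": np.where(annotated, "generic class", "unknown"),
            "subclass": np.where(annotated, "generic subclass", "unknown"),
        },
        index=mets,
    )
    truth.annotated = pd.Series(annotated, index=mets, name="annotated")

    non_flat = [m for m, l in zip(mets, labels) if l != "flat"]
    disc = set(non_flat[: config.n_discriminative])
    truth.discriminative_metabolites = disc
    coupled_mets = non_flat[
        config.n_discriminative : config.n_discriminative + config.coupled_block_size[1]
    ]
    truth.coupled_metabolites = list(coupled_mets)

    sig = (
        truth.block_signal.set_index(["bird", "dph"])["z"]
        if len(truth.block_signal)
        else pd.Series(dtype=float)
    )
    base_log = rng.uniform(4, 7, size=n)
    day_index = {d: i for i, d in enumerate(days)}
    rows = {}
    for bird in birds:
        for day in days:
            sid = f"{bird}_{day:02d}d_serum"
            ti = day_index[day]
            logv = base_log.copy()
            for j, lab in enumerate(labels):
                if lab != "flat":
                    amp = config.metabolite_amplitude
                    if mets[j] in disc:
                        amp *= 2.0
                    logv[j] += amp * config.cluster_trajectories[lab][ti]
            if len(sig):
                z = sig.get((bird, day), 0.0)
                for m in coupled_mets:
                    logv[mets.index(m)] += config.coupling_strength * z
            logv += rng.normal(0, config.metabolite_noise_sd, size=n)
            rows[sid] = 10.0**logv
    data = pd.DataFrame.from_dict(rows, orient="index", columns=mets)
    # rare features: zero out in most samples to exercise the prevalence filter
    n_rare = int(round(config.rare_metabolite_fraction * n))
    rare = rng.choice(n, size=n_rare, replace=False)
    for j in rare:
        zero_rows = rng.random(len(data)) < 0.85
        data.iloc[zero_rows, j] = 0.0
    truth.metabolite_taxonomy = taxonomy
    return data


@dataclass
class SimulatedStudy:
    config: SimConfig
    tables: dict
    loads: pd.DataFrame
    trees: dict
    truth: GroundTruth
    metabolites: pd.DataFrame
    metabolite_taxonomy: pd.DataFrame
    metabolite_dph: pd.Series


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """One-call convenience wrapper running both generators."""
    config = config or SimConfig()
    tables, loads, trees, truth = simulate_microbiome(config)
    metabolites = simulate_metabolome(config, truth)
    taxonomy = truth.metabolite_taxonomy
    dph = pd.Series(
        {sid: int(sid.split("_")[1].rstrip("d")) for sid in metabolites.index},
        name="dph",
    )
    return SimulatedStudy(config, tables, loads, trees, truth, metabolites, taxonomy, dph)
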