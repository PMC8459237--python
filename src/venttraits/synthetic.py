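"""Synthetic trait tables and colonization time series with known ground truth.

The generator emulates the two data products of a vent colonization study:

* a species x trait modality table built by planting G guild *templates*
  (one modality per trait) and copying each template to its member species
  with a per-trait flip probability (ordered traits flip to an adjacent
  level, so the flip probability controls ordinal distortion smoothly) and a
  per-cell missing probability;
* per-surface counts whose expected species composition follows a
  quadratic-in-time log-linear model, p(t) = softmax(b0 + b1 t + b2 t^2),
  sampled multinomially per surface. This is the exact generative dual of the
  multinomial logit fitted downstream, so parameter recovery is well posed.

All randomness flows from a single seed; fixtures are reproducible
byte-for-byte.

The module also ships a synthetic reconstruction of the East Pacific Rise
post-eruption study system (``reference_community``) built from published
summary tables rather than raw data: 12 functional guilds covering 58
species, trait definitions for the 8 study traits, 30 post-eruption
sandwiches within the 1.9-6.5 degC recovery-temperature window across 7
recovery times plus 6 pre-eruption basalt blocks, and guild-level abundance
trends that echo the observed succession (symbiont-hosting tubeworms
dominant early, grazers peaking mid-series, carnivores and suspension
feeders rising late).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trait_data import (AbundanceTable, SampleRecord, TraitSpec, TraitTable,
                         read_abundance, read_trait_table)

# ---------------------------------------------------------------------------
# Default trait set: the eight study traits and their modalities
# ---------------------------------------------------------------------------

DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("maximum adult body size", "ordered",
              ("small (~1 mm)", "medium (~10 mm)", "large (~100 mm)",
               "very large (~1,000 mm)")),
    TraitSpec("habitat complexity", "categorical",
              ("does not add complexity", "mat forming (<10 cm)",
               "bed forming (>10 cm)", "open bush forming",
               "dense bush forming")),
    TraitSpec("trophic mode", "ordered",
              ("symbiont", "bacterivore", "detritivore", "carnivore S",
               "carnivore O")),
    TraitSpec("feeding method", "categorical",
              ("non-feeding", "deposit feeder", "suspension feeder",
               "predator", "parasite or commensal")),
    TraitSpec("relative adult mobility", "ordered",
              ("sessile", "movement restricted", "crawler", "freely mobile")),
    TraitSpec("external protection", "ordered",
              ("soft bodied", "moderately protected", "well protected")),
    TraitSpec("larval development", "categorical",
              ("lecithotrophic", "planktotrophic", "brooding", "direct")),
    TraitSpec("reproductive type", "categorical",
              ("gonochoristic", "hermaphroditic", "asexual")),
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic community generator.

    ``modality_flip_prob`` is the per-trait probability that a species
    deviates from its guild template; ``missing_prob`` the per-cell missing
    probability. ``beta`` holds per-guild quadratic trend coefficients
    (n_guilds x 3, month scale); species inherit their guild's trend with the
    guild's expected share split equally among members.
    """

    n_species: int = 58
    n_guilds: int = 12
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    modality_flip_prob: float = 0.05
    missing_prob: float = 0.02
    times: tuple[float, ...] = (9, 22, 33, 53, 66, 96, 135)
    surfaces_per_time: tuple[int, ...] = (5, 5, 4, 4, 4, 4, 4)
    mean_individuals_per_surface: float = 300.0
    temp_window: tuple[float, float] = (1.9, 6.5)
    beta: np.ndarray | None = None  # n_guilds x 3; default: no trend
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.modality_flip_prob <= 1):
            raise ValueError("modality_flip_prob must be in [0, 1]")
        if not (0 <= self.missing_prob <= 1):
            raise ValueError("missing_prob must be in [0, 1]")
        if len(self.times) < 2:
            raise ValueError("need >=2 time points")
        if len(self.surfaces_per_time) != len(self.times):
            raise ValueError("surfaces_per_time must align with times")
        if self.mean_individuals_per_surface <= 0:
            raise ValueError("mean_individuals_per_surface must be positive")
        if self.n_species < self.n_guilds:
            raise ValueError("need at least one species per guild")


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    streams = {"traits": 0, "abundance": 1, "meta": 2}
    return np.random.default_rng(ss.spawn(max(streams.values()) + 1)[streams[stream]])


# ---------------------------------------------------------------------------
# Trait-table generation
# ---------------------------------------------------------------------------


def make_traits(config: SynthConfig):
    """Plant guild templates and emit a noisy species x trait table.

    Returns ``(specs, trait_table, true_guilds)`` where ``true_guilds`` is a
    Series mapping species to their planted guild (ground truth for recovery
    experiments). Templates are drawn uniformly per trait and redrawn until
    all pairwise distinct; species are assigned to guilds round-robin.
    """
    rng = _rng(config, "traits")
    specs = list(config.traits)
    G = config.n_guilds

    for _ in range(1000):
        templates = [[rng.choice(s.levels) for s in specs] for _ in range(G)]
        if len({tuple(t) for t in templates}) == G:
            break
    else:
        raise ValueError("could not draw distinct guild templates")

    species = [f"sp{i:03d}" for i in range(config.n_species)]
    guilds = pd.Series([i % G for i in range(config.n_species)], index=species,
                       name="guild")
    rows = {}
    for sp in species:
        tpl = templates[guilds[sp]]
        row = {}
        for spec, value in zip(specs, tpl):
            if rng.random() < config.modality_flip_prob:
                if spec.kind == "ordered":
                    i = spec.rank_of(value)
                    nbrs = [j for j in (i - 1, i + 1) if 0 <= j < len(spec.levels)]
                    value = spec.levels[rng.choice(nbrs)]
                else:
                    others = [l for l in spec.levels if l != value]
                    value = rng.choice(others)
            row[spec.name] = value
        # missing values, but never blank out the whole species
        missing = rng.random(len(specs)) < config.missing_prob
        if missing.all():
            missing[rng.integers(len(specs))] = False
        for spec, m in zip(specs, missing):
            if m:
                row[spec.name] = np.nan
        rows[sp] = row
    data = pd.DataFrame.from_dict(rows, orient="index")[[s.name for s in specs]]
    return specs, TraitTable(data, specs), guilds


# ---------------------------------------------------------------------------
# Abundance generation
# ---------------------------------------------------------------------------


def species_betas(config: SynthConfig, true_guilds: pd.Series) -> pd.DataFrame:
    """Species-level softmax coefficients implied by the guild-level trends."""
    G = config.n_guilds
    beta = np.zeros((G, 3)) if config.beta is None else np.asarray(config.beta, float)
    if beta.shape != (G, 3):
        raise ValueError(f"beta must be (n_guilds, 3), got {beta.shape}")
    sizes = true_guilds.value_counts()
    rows = {}
    for sp in true_guilds.index:
        g = true_guilds[sp]
        b0 = beta[g, 0] - np.log(sizes[g])  # split the guild share equally
        rows[sp] = (b0, beta[g, 1], beta[g, 2])
    return pd.DataFrame(rows, index=["b0", "b1", "b2"]).T


def composition_at(betas: pd.DataFrame, t: float) -> np.ndarray:
    """Expected species relative abundances at time t (softmax of quadratic)."""
    eta = (betas["b0"] + betas["b1"] * t + betas["b2"] * t * t).to_numpy()
    eta = eta - eta.max()
    p = np.exp(eta)
    return p / p.sum()


def make_abundances(config: SynthConfig, true_guilds: pd.Series,
                    n_pre_surfaces: int = 0,
                    pre_reference_months: float = 85.0,
                    extra_taxa: int = 0,
                    out_of_window: int = 0) -> AbundanceTable:
    """Sample per-surface multinomial counts from the planted trend model.

    Per time point ``surfaces_per_time`` sandwiches are drawn, each with a
    Poisson number of individuals distributed multinomially according to the
    softmax composition at that time. Recovery temperatures are uniform in
    the configured window. Optionally adds ``n_pre_surfaces`` pre-eruption
    blocks (composition evaluated at ``pre_reference_months``, the age of the
    mature reference community), ``extra_taxa`` taxa without trait data
    (sprinkled as rare finds), and ``out_of_window`` early surfaces with
    recovery temperatures above the window (removed by the analysis filter).
    """
    rng = _rng(config, "abundance")
    betas = species_betas(config, true_guilds)
    species = list(true_guilds.index)
    taxa = species + [f"untraited{j:02d}" for j in range(extra_taxa)]
    lo, hi = config.temp_window

    records: list[SampleRecord] = []
    counts: list[np.ndarray] = []

    def draw_surface(sid, kind, epoch, t_label, temp, dep, t_comp):
        p = composition_at(betas, t_comp)
        n = rng.poisson(config.mean_individuals_per_surface)
        c = rng.multinomial(n, p) if n > 0 else np.zeros(len(species), int)
        row = np.zeros(len(taxa), dtype=int)
        row[:len(species)] = c
        if extra_taxa:
            row[len(species):] = rng.poisson(0.5, size=extra_taxa)
        records.append(SampleRecord(sid, kind, epoch, t_label, temp, dep))
        counts.append(row)

    k = 0
    for t, n_surf in zip(config.times, config.surfaces_per_time):
        for _ in range(n_surf):
            temp = float(rng.uniform(lo, hi))
            dep = float(min(t, rng.uniform(6, 24)))
            draw_surface(f"S{k:03d}", "sandwich", "post_eruption", float(t),
                         temp, dep, float(t))
            k += 1
    for j in range(out_of_window):
        t = float(config.times[j % 2])  # hot surfaces only existed early
        temp = float(rng.uniform(hi + 0.5, hi + 20.0))
        draw_surface(f"S{k:03d}", "sandwich", "post_eruption", t, temp,
                     float(min(t, 12.0)), t)
        k += 1
    for j in range(n_pre_surfaces):
        temp = float(rng.uniform(lo, hi))
        draw_surface(f"B{j:03d}", "block", "pre_eruption", None, temp, 37.0,
                     pre_reference_months)

    frame = pd.DataFrame(counts, index=[r.sample_id for r in records],
                         columns=taxa)
    return AbundanceTable(records, frame)


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------


def write_fixture(config: SynthConfig, out_dir, **abundance_kwargs) -> dict:
    """Write a complete CSV fixture in the schemas the readers consume.

    Emits ``trait_definitions.csv``, ``species_modalities.csv`` (long form),
    ``counts.csv`` (long form), ``sample_metadata.csv``, and
    ``ground_truth.json`` (true guilds, guild trend coefficients, seed).
    Returns the file paths. Two runs with the same config produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs, table, guilds = make_traits(config)
    abundance = make_abundances(config, guilds, **abundance_kwargs)

    defs = pd.DataFrame([(s.name, s.kind, lvl) for s in specs for lvl in s.levels],
                        columns=["trait", "trait_type", "modality"])
    defs.to_csv(out / "trait_definitions.csv", index=False)

    long_rows = [(sp, tr, table.data.at[sp, tr])
                 for sp in table.species for tr in table.traits
                 if pd.notna(table.data.at[sp, tr])]
    pd.DataFrame(long_rows, columns=["species", "trait", "modality"]).to_csv(
        out / "species_modalities.csv", index=False)

    counts_long = (abundance.counts.rename_axis("sample").reset_index()
                   .melt(id_vars="sample", var_name="species", value_name="count"))
    counts_long.to_csv(out / "counts.csv", index=False)

    meta = pd.DataFrame([{
        "sample_id": r.sample_id, "surface_kind": r.surface_kind,
        "epoch": r.epoch, "time_months": r.time_months,
        "recovery_temp_C": r.recovery_temp_C,
        "deployment_months": r.deployment_months,
    } for r in abundance.samples])
    meta.to_csv(out / "sample_metadata.csv", index=False)

    beta = (np.zeros((config.n_guilds, 3)) if config.beta is None
            else np.asarray(config.beta, float))
    truth = {
        "seed": config.seed,
        "true_guilds": {sp: int(g) for sp, g in guilds.items()},
        "guild_beta": beta.tolist(),
        "times": list(config.times),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1,
                                                      sort_keys=True))
    return {name: out / name for name in
            ("trait_definitions.csv", "species_modalities.csv", "counts.csv",
             "sample_metadata.csv", "ground_truth.json")}


def read_fixture(fixture_dir):
    """Read a fixture directory back into (specs, TraitTable, AbundanceTable)."""
    d = Path(fixture_dir)
    specs, table = read_trait_table(d / "trait_definitions.csv",
                                    d / "species_modalities.csv")
    abundance = read_abundance(d / "counts.csv", d / "sample_metadata.csv")
    return specs, table, abundance


# ---------------------------------------------------------------------------
# Synthetic reconstruction of the study community
# ---------------------------------------------------------------------------

#: combined feeding-method levels used by some guilds (declared as distinct
#: categorical levels)
_FEEDING_EXTENDED = ("non-feeding", "deposit feeder", "suspension feeder",
                     "predator", "parasite or commensal",
                     "deposit feeder/suspension feeder",
                     "deposit feeder/predator", "suspension feeder/predator")

REFERENCE_TRAITS: tuple[TraitSpec, ...] = tuple(
    TraitSpec(s.name, s.kind, _FEEDING_EXTENDED) if s.name == "feeding method"
    else s
    for s in DEFAULT_TRAITS)

# 12 guilds: (name, n_species, modality per trait in DEFAULT_TRAITS order;
# None = not scored). Sizes sum to 58.
REFERENCE_GUILDS: tuple[tuple[str, int, tuple], ...] = (
    ("A", 21, ("medium (~10 mm)", "does not add complexity", "bacterivore",
               "deposit feeder", "crawler", "well protected",
               "lecithotrophic", "gonochoristic")),
    ("B", 4, ("medium (~10 mm)", "does not add complexity", "detritivore",
              "deposit feeder/suspension feeder", "crawler", "soft bodied",
              "lecithotrophic", None)),
    ("C", 2, ("small (~1 mm)", "does not add complexity", "bacterivore",
              "deposit feeder", "crawler", "moderately protected",
              "lecithotrophic", "hermaphroditic")),
    ("D", 3, ("large (~100 mm)", "does not add complexity", "carnivore S",
              "deposit feeder", "crawler", "well protected",
              "planktotrophic", None)),
    ("E", 12, ("medium (~10 mm)", "does not add complexity", "carnivore O",
               "deposit feeder/predator", "crawler", "moderately protected",
               None, "gonochoristic")),
    ("F", 2, ("large (~100 mm)", "bed forming (>10 cm)", "detritivore",
              "suspension feeder", "movement restricted", "well protected",
              "planktotrophic", "hermaphroditic")),
    ("G", 3, ("large (~100 mm)", "does not add complexity", "detritivore",
              "suspension feeder", "sessile", "well protected", None, None)),
    ("H", 2, ("large (~100 mm)", "does not add complexity", "carnivore S",
              "predator", "freely mobile", "well protected",
              "planktotrophic", "gonochoristic")),
    ("I", 3, ("large (~100 mm)", "dense bush forming", "symbiont",
              "non-feeding", "sessile", "well protected", "lecithotrophic",
              "gonochoristic")),
    ("J", 2, ("medium (~10 mm)", "does not add complexity", "detritivore",
              "deposit feeder", "crawler", "well protected", "brooding",
              "gonochoristic")),
    ("K", 2, ("small (~1 mm)", "does not add complexity", "carnivore O",
              "deposit feeder", "crawler", "moderately protected", "direct",
              "gonochoristic")),
    ("L", 2, ("large (~100 mm)", "does not add complexity", "carnivore O",
              "suspension feeder/predator", "sessile", "soft bodied",
              "planktotrophic", "asexual")),
)

#: guild-level succession trends: a hump peaked at t_star with contrast c on
#: the 135-month scale, or a monotone rise; chosen to echo the observed
#: succession (I crashes early; A, B, F peak ~22 months; E, G, J, L rise).
_S = 135.0
_REFERENCE_TRENDS = {
    # guild: (baseline, peak_month_or_None, contrast)
    "A": (2.5, 22.0, 5.0),
    "B": (0.5, 22.0, 4.0),
    "C": (0.0, None, 0.0),
    "D": (-0.5, None, 0.0),
    "E": (0.0, None, 3.0),   # monotone rise
    "F": (0.3, 22.0, 4.0),
    "G": (-0.5, None, 3.0),  # monotone rise
    "H": (-1.0, None, 0.0),
    "I": (2.0, 0.0, 6.0),    # peak at the eruption: early dominance, crash
    "J": (-1.0, None, 3.0),  # monotone rise
    "K": (-1.0, None, 0.0),
    "L": (-1.0, None, 2.0),  # monotone rise
}


def _trend_beta() -> np.ndarray:
    beta = np.zeros((len(REFERENCE_GUILDS), 3))
    for g, (name, _, _) in enumerate(REFERENCE_GUILDS):
        b, t_star, c = _REFERENCE_TRENDS[name]
        if c == 0.0:
            beta[g] = (b, 0.0, 0.0)
        elif t_star is None:  # monotone rise
            beta[g] = (b, c / _S, 0.0)
        else:  # hump with vertex at t_star
            b2 = -c / _S ** 2
            beta[g] = (b, -2 * b2 * t_star, b2)
    return beta


def reference_community(seed: int = 0, flip_prob: float = 0.0):
    """Synthetic reconstruction of the post-eruption study system.

    Returns ``(config, specs, trait_table, true_guilds)`` where the trait
    table realizes the 12 published guild templates over 58 species
    (templates copied exactly at ``flip_prob=0``; Table cells not scored for
    a guild become missing values). Species are named ``<guild>_sp<i>``.
    """
    specs = list(REFERENCE_TRAITS)
    rows = {}
    labels = {}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 12)))
    for g, (name, n, template) in enumerate(REFERENCE_GUILDS):
        for i in range(n):
            sp = f"{name}_sp{i:02d}"
            row = {}
            for spec, value in zip(specs, template):
                if value is not None and flip_prob and rng.random() < flip_prob:
                    if spec.kind == "ordered":
                        j = spec.rank_of(value)
                        nbrs = [x for x in (j - 1, j + 1)
                                if 0 <= x < len(spec.levels)]
                        value = spec.levels[rng.choice(nbrs)]
                    else:
                        value = rng.choice([l for l in spec.levels if l != value])
                row[spec.name] = value if value is not None else np.nan
            rows[sp] = row
            labels[sp] = g
    data = pd.DataFrame.from_dict(rows, orient="index")[[s.name for s in specs]]
    table = TraitTable(data, specs)
    guilds = pd.Series(labels, name="guild")
    config = SynthConfig(
        n_species=58, n_guilds=12, traits=tuple(specs),
        modality_flip_prob=flip_prob, missing_prob=0.0,
        times=(9, 22, 33, 53, 66, 96, 135),
        surfaces_per_time=(5, 5, 4, 4, 4, 4, 4),
        mean_individuals_per_surface=300.0,
        beta=_trend_beta(), seed=seed)
    return config, specs, table, guilds


def write_reference_fixture(out_dir, seed: int = 0) -> dict:
    """Write the full reconstruction fixture: 42 surfaces (30 in-window
    post-eruption + 6 hot early surfaces + 6 pre-eruption blocks), 68 taxa of
    which 58 carry trait data."""
    config, specs, table, guilds = reference_community(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    defs = pd.DataFrame([(s.name, s.kind, lvl) for s in specs for lvl in s.levels],
                        columns=["trait", "trait_type", "modality"])
    defs.to_csv(out / "trait_definitions.csv", index=False)
    long_rows = [(sp, tr, table.data.at[sp, tr])
                 for sp in table.species for tr in table.traits
                 if pd.notna(table.data.at[sp, tr])]
    pd.DataFrame(long_rows, columns=["species", "trait", "modality"]).to_csv(
        out / "species_modalities.csv", index=False)

    abundance = make_abundances(config, guilds, n_pre_surfaces=6,
                                pre_reference_months=85.0, extra_taxa=10,
                                out_of_window=6)
    counts_long = (abundance.counts.rename_axis("sample").reset_index()
                   .melt(id_vars="sample", var_name="species", value_name="count"))
    counts_long.to_csv(out / "counts.csv", index=False)
    meta = pd.DataFrame([{
        "sample_id": r.sample_id, "surface_kind": r.surface_kind,
        "epoch": r.epoch, "time_months": r.time_months,
        "recovery_temp_C": r.recovery_temp_C,
        "deployment_months": r.deployment_months,
    } for r in abundance.samples])
    meta.to_csv(out / "sample_metadata.csv", index=False)
    truth = {"seed": seed,
             "true_guilds": {sp: int(g) for sp, g in guilds.items()},
             "guild_beta": _trend_beta().tolist(),
             "times": list(config.times)}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1,
                                                      sort_keys=True))
    return {name: out / name for name in
            ("trait_definitions.csv", "species_modalities.csv", "counts.csv",
             "sample_metadata.csv", "ground_truth.json")}
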