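"""Synthetic reciprocal-transplant study generator.

Emulates a five-site climate-gradient reciprocal transplant (desert,
scrubland, grassland, pine-oak, subalpine): litter bags carrying each site's
inoculum are deployed at every site in four replicates over three collection
time points, with native-litter survey samples taken alongside. The generator
produces, with known ground truth,

* the study design and its sample bookkeeping,
* per-sample clade mixtures under three scenarios — ``climate`` (composition
  tracks the destination site), ``substrate`` (all transplants converge on the
  grassland composition because they share grassland litter), ``null`` (one
  shared composition),
* tabular protein-alignment hit files (BLAST outfmt-6 dialect) whose identity
  ties and decoys exercise the clade/pseudo-clade classifier, and
* a random row-stochastic clade x trait matrix.

Sequences themselves are never simulated; the hit table is the boundary.
Randomness fans out from one global seed to per-sample substreams keyed by
sample id (a CRC32 counter scheme), so adding samples never reshuffles the
draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .labels import (
    BACKGROUND,
    GRASSLAND,
    MAIN_CLADES,
    N_CLADES,
    SITES,
    TRAIT_CATEGORIES,
    pseudo_label,
)

HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
)

#: identity grid used for simulated hits; exact ties are constructible because
#: every value round-trips through its 1-decimal text form.
IDENTITY_GRID = (98.0, 98.7, 100.0)

SCENARIOS = ("climate", "substrate", "null")


def rng_for(seed: int, *keys: str) -> np.random.Generator:
    """Substream generator for (seed, keys): stable under sample-set growth."""
    entropy = [int(seed)] + [zlib.crc32(k.encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """The crossed transplant design plus adjacent survey sampling.

    ``missing_slots`` are (site, inoculum, timepoint, replicate) tuples of
    deployed bags that yielded no sequenced metagenome; they reduce sequenced
    sample counts, not deployment counts.
    """

    sites: tuple[str, ...]
    inocula: tuple[str, ...]
    n_replicates: int
    timepoints: tuple[str, ...]
    missing_slots: tuple[tuple[str, str, str, str], ...] = ()
    survey_counts: int = 4  # survey samples per site at a surveyed timepoint

    @property
    def total_deployed(self) -> int:
        return (
            len(self.sites) * len(self.inocula) * self.n_replicates * len(self.timepoints)
        )

    @property
    def collected_per_timepoint(self) -> int:
        return len(self.sites) * len(self.inocula) * self.n_replicates

    def transplant_samples(self, timepoint: str) -> int:
        """Sequenced transplant metagenomes at one timepoint."""
        if timepoint not in self.timepoints:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        missing = sum(1 for s in self.missing_slots if s[2] == timepoint)
        return self.collected_per_timepoint - missing

    def replicate_labels(self) -> tuple[str, ...]:
        return tuple(f"r{i}" for i in range(1, self.n_replicates + 1))

    def metadata(self, timepoint: str, include_survey: bool = True) -> pd.DataFrame:
        """Sample table for one timepoint: sample_id, site, inoculum, type."""
        if timepoint not in self.timepoints:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        missing = set(self.missing_slots)
        rows = []
        for site in self.sites:
            for inoc in self.inocula:
                for rep in self.replicate_labels():
                    if (site, inoc, timepoint, rep) in missing:
                        continue
                    rows.append(
                        {
                            "sample_id": f"{timepoint}-{site}-{inoc}-{rep}",
                            "site": site,
                            "inoculum": inoc,
                            "timepoint": timepoint,
                            "replicate": rep,
                            "type": "transplant",
                        }
                    )
        if include_survey:
            for site in self.sites:
                for i in range(1, self.survey_counts + 1):
                    rows.append(
                        {
                            "sample_id": f"{timepoint}-survey-{site}-r{i}",
                            "site": site,
                            "inoculum": site,
                            "timepoint": timepoint,
                            "replicate": f"r{i}",
                            "type": "survey",
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")


def build_design(
    n_sites: int = 5,
    n_inocula: int = 5,
    n_replicates: int = 4,
    n_timepoints: int = 3,
    missing_slots=(),
    survey_counts: int = 4,
) -> StudyDesign:
    """Construct a reciprocal-transplant design.

    With the default shape this reproduces the field experiment: 5 sites x
    5 inocula x 4 replicates x 3 collection timepoints = 300 deployed bags,
    100 collected per timepoint. Site labels are the climate-gradient names
    when the counts fit, generic ``site<i>`` labels otherwise; collection
    timepoints are labelled T1..Tn (T0 is the deployment baseline).
    """
    for name, v in [
        ("n_sites", n_sites),
        ("n_inocula", n_inocula),
        ("n_replicates", n_replicates),
        ("n_timepoints", n_timepoints),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    sites = SITES[:n_sites] if n_sites <= len(SITES) else tuple(
        f"site{i}" for i in range(1, n_sites + 1)
    )
    inocula = SITES[:n_inocula] if n_inocula <= len(SITES) else tuple(
        f"site{i}" for i in range(1, n_inocula + 1)
    )
    timepoints = tuple(f"T{i}" for i in range(1, n_timepoints + 1))
    reps = tuple(f"r{i}" for i in range(1, n_replicates + 1))
    norm = []
    for slot in missing_slots:
        site, inoc, tp, rep = slot
        rep = rep if isinstance(rep, str) else f"r{rep}"
        for value, universe, what in [
            (site, sites, "site"),
            (inoc, inocula, "inoculum"),
            (tp, timepoints, "timepoint"),
            (rep, reps, "replicate"),
        ]:
            if value not in universe:
                raise ValueError(
                    f"missing slot {slot!r}: {what} {value!r} is not in the design"
                )
        norm.append((site, inoc, tp, rep))
    return StudyDesign(
        sites=sites,
        inocula=inocula,
        n_replicates=n_replicates,
        timepoints=timepoints,
        missing_slots=tuple(norm),
        survey_counts=survey_counts,
    )


# ---------------------------------------------------------------------------
# scenarios and clade mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of one simulation scenario.

    ``clade_means`` maps a condition key (a site name, or ``"null"``) to a
    strictly positive Dirichlet concentration vector over the 12 clades;
    ``ambiguity_rate`` is the fraction of non-decoy reads whose hits tie
    across >= 2 clades (forcing a pseudo-clade call) and defaults to the
    pseudo-clade fraction observed in the real dataset (~0.3);
    ``decoy_fraction`` reads hit only background entries or fall below the
    identity/E-value filters.
    """

    scenario: str = "climate"
    clade_means: dict[str, np.ndarray] | None = None
    reads_per_sample: int = 300
    ambiguity_rate: float = 0.3
    decoy_fraction: float = 0.2
    forced_tie_set: tuple[int, ...] | None = None
    seed: int = 1

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must be in [0, 1]")
        if self.clade_means is not None:
            for key, alpha in self.clade_means.items():
                a = np.asarray(alpha, dtype=float)
                if a.shape != (N_CLADES,) or np.any(a <= 0):
                    raise ValueError(
                        f"concentration vector for {key!r} must be {N_CLADES} "
                        "strictly positive values"
                    )

    def resolved_means(self, sites) -> dict[str, np.ndarray]:
        if self.clade_means is not None:
            return {k: np.asarray(v, float) for k, v in self.clade_means.items()}
        return default_clade_means(sites)


def default_clade_means(sites, alpha_dominant: float = 6.0, alpha_base: float = 0.4):
    """Per-site Dirichlet concentrations with two dominant clades per site.

    Site i favours clades 2i+1 and 2i+2 (desert: 1,2; scrubland: 3,4; ...)
    so site compositions are well separated while replicates still vary.
    Also supplies a flat ``"null"`` vector for the null scenario.
    """
    means: dict[str, np.ndarray] = {}
    for i, site in enumerate(sites):
        alpha = np.full(N_CLADES, alpha_base)
        alpha[(2 * i) % N_CLADES] = alpha_dominant
        alpha[(2 * i + 1) % N_CLADES] = alpha_dominant
        means[site] = alpha
    means["null"] = np.full(N_CLADES, 1.0)
    return means


def condition_for_sample(row: pd.Series, scenario: str) -> str:
    """The condition key whose concentration vector a sample is drawn from."""
    if scenario == "null":
        return "null"
    if row["type"] == "survey":
        return row["site"]
    if scenario == "climate":
        return row["site"]
    # substrate: shared grassland litter pulls every transplant to grassland
    return GRASSLAND


def simulate_clade_mixtures(
    design: StudyDesign, params: ScenarioParams, timepoint: str | None = None
) -> pd.DataFrame:
    """Ground-truth clade proportion vectors, one Dirichlet draw per sample.

    Returns samples x 12 clades, each row on the simplex. Reproducible for a
    fixed seed and independent of sample order.
    """
    timepoint = timepoint or design.timepoints[-1]
    md = design.metadata(timepoint)
    means = params.resolved_means(design.sites)
    rows = {}
    for sample_id, row in md.iterrows():
        cond = condition_for_sample(row, params.scenario)
        if cond not in means:
            raise KeyError(
                f"no concentration vector for condition {cond!r} "
                f"(needed by sample {sample_id!r})"
            )
        rng = rng_for(params.seed, "mixture", sample_id)
        rows[sample_id] = rng.dirichlet(means[cond])
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(MAIN_CLADES))
    return table.loc[md.index]


def simulate_clade_counts(
    design: StudyDesign, params: ScenarioParams, timepoint: str | None = None
) -> pd.DataFrame:
    """Multinomial clade counts drawn from each sample's mixture.

    A shortcut past the hit-table layer for statistics-level experiments:
    counts have the same ground truth as the full simulate -> classify route
    but none of the classification ambiguity.
    """
    mixtures = simulate_clade_mixtures(design, params, timepoint)
    out = {}
    for sample_id, p in mixtures.iterrows():
        rng = rng_for(params.seed, "counts", sample_id)
        out[sample_id] = rng.multinomial(params.reads_per_sample, p.to_numpy())
    return pd.DataFrame.from_dict(out, orient="index", columns=list(MAIN_CLADES)).loc[
        mixtures.index
    ]


# ---------------------------------------------------------------------------
# marker reference database and hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerDatabase:
    """Reference entries: (entry_id, genome_id, clade, core_gene).

    Non-background entries carry a clade in "1".."12" and a core-gene id;
    background entries mimic the non-target protein space that competitive
    decoy hits land on.
    """

    entries: tuple[tuple[str, str, str, str], ...]
    by_clade: dict[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("entry ids must be unique")
        by: dict[str, list[str]] = {}
        for entry_id, _genome, clade, gene in self.entries:
            if clade != BACKGROUND and not gene:
                raise ValueError(f"entry {entry_id!r} lacks a core gene")
            by.setdefault(clade, []).append(entry_id)
        object.__setattr__(self, "by_clade", {k: tuple(v) for k, v in by.items()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.entries), columns=["entry_id", "genome_id", "clade", "core_gene"]
        ).set_index("entry_id")


def build_marker_database(
    n_genomes_per_clade: int = 2, n_core_genes: int = 23, n_background: int = 40
) -> MarkerDatabase:
    """Reference database: 23 marker core genes per genome, 12 clades, decoys."""
    entries = []
    for clade in MAIN_CLADES:
        for g in range(1, n_genomes_per_clade + 1):
            genome = f"genome_c{clade}_{g}"
            for k in range(1, n_core_genes + 1):
                entries.append((f"{genome}|cg{k:02d}", genome, clade, f"cg{k:02d}"))
    for b in range(1, n_background + 1):
        entries.append((f"bg{b:04d}", f"bg_genome{b:04d}", BACKGROUND, ""))
    return MarkerDatabase(entries=tuple(entries))


def _decoy_hits(qid: str, database: MarkerDatabase, rng: np.random.Generator) -> list[dict]:
    """Hits that the identity/E-value/background filters must remove."""
    kind = rng.integers(3)
    if kind == 0:  # background-only, otherwise passes the numeric filters
        subs = rng.choice(database.by_clade[BACKGROUND], size=rng.integers(1, 4), replace=False)
        return [
            {"subject_id": s, "pct_identity": 100.0, "evalue": 1e-30} for s in subs
        ]
    clade = str(rng.integers(1, N_CLADES + 1))
    sub = rng.choice(database.by_clade[clade])
    if kind == 1:  # identity below 98
        return [{"subject_id": sub, "pct_identity": 95.0, "evalue": 1e-30}]
    return [{"subject_id": sub, "pct_identity": 98.7, "evalue": 1e-15}]  # weak E-value


def _passing_evalue(rng: np.random.Generator) -> float:
    return float(10.0 ** -rng.uniform(25.0, 60.0))


def simulate_sample_hits(
    sample_id: str,
    mixture,
    database: MarkerDatabase,
    params: ScenarioParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One sample's simulated alignment table, in BLAST outfmt-6 columns.

    Each read draws its true clade from ``mixture``; its hits land on that
    clade's reference entries at a top identity from the 98/98.7/100 grid.
    With probability ``ambiguity_rate`` one or two other clades also receive
    hits at exactly the top identity, forcing a pseudo-clade call downstream;
    ``decoy_fraction`` reads produce background-only or sub-threshold hits.

    Returns ``(hits, truth)`` where truth has one row per read with its
    expected classification label (``decoy`` reads expect ``discarded``).
    """
    p = np.asarray(mixture, dtype=float)
    if p.shape != (N_CLADES,) or p.sum() <= 0:
        raise ValueError(f"mixture for {sample_id!r} must be a positive 12-vector")
    p = p / p.sum()
    rng = rng_for(params.seed, "hits", sample_id)
    hit_rows: list[dict] = []
    truth_rows: list[dict] = []
    for q in range(params.reads_per_sample):
        qid = f"{sample_id}|q{q:05d}"
        if rng.random() < params.decoy_fraction:
            partial = _decoy_hits(qid, database, rng)
            truth_rows.append({"query_id": qid, "true_label": "discarded", "decoy": True})
        else:
            if params.forced_tie_set:
                tie = sorted(set(int(c) for c in params.forced_tie_set))
                true_clade = str(tie[0])
            else:
                true_clade = str(rng.choice(N_CLADES, p=p) + 1)
                tie = [int(true_clade)]
                if rng.random() < params.ambiguity_rate:
                    others = [c for c in range(1, N_CLADES + 1) if c != int(true_clade)]
                    extra = rng.choice(others, size=rng.integers(1, 3), replace=False)
                    tie = sorted({int(true_clade), *map(int, extra)})
            top = float(rng.choice(IDENTITY_GRID))
            partial = []
            for clade_i in tie:
                entries = database.by_clade[str(clade_i)]
                n_top = int(rng.integers(1, min(4, len(entries)) + 1))
                for sub in rng.choice(entries, size=n_top, replace=False):
                    partial.append(
                        {"subject_id": sub, "pct_identity": top, "evalue": _passing_evalue(rng)}
                    )
            # sub-top hits to other clades must never affect the call
            lower = [g for g in IDENTITY_GRID if g < top]
            if lower and rng.random() < 0.5:
                clade_i = int(rng.integers(1, N_CLADES + 1))
                sub = rng.choice(database.by_clade[str(clade_i)])
                partial.append(
                    {
                        "subject_id": sub,
                        "pct_identity": float(rng.choice(lower)),
                        "evalue": _passing_evalue(rng),
                    }
                )
            label = str(tie[0]) if len(tie) == 1 else pseudo_label(tie)
            truth_rows.append({"query_id": qid, "true_label": label, "decoy": False})
        for h in partial:
            aln = int(rng.integers(40, 51))
            mism = int(round(aln * (100.0 - h["pct_identity"]) / 100.0))
            hit_rows.append(
                {
                    "query_id": qid,
                    "subject_id": h["subject_id"],
                    "pct_identity": round(h["pct_identity"], 1),
                    "aln_length": aln,
                    "mismatches": mism,
                    "gap_opens": 0,
                    "q_start": 1,
                    "q_end": aln * 3,
                    "s_start": 1,
                    "s_end": aln,
                    "evalue": h["evalue"],
                    "bit_score": round(aln * h["pct_identity"] / 50.0, 1),
                }
            )
    hits = pd.DataFrame(hit_rows, columns=list(HIT_COLUMNS))
    truth = pd.DataFrame(truth_rows, columns=["query_id", "true_label", "decoy"])
    return hits, truth


def simulate_hit_tables(
    design: StudyDesign, params: ScenarioParams, timepoint: str | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, MarkerDatabase]:
    """Hit tables for every sample at a timepoint, plus pooled truth."""
    mixtures = simulate_clade_mixtures(design, params, timepoint)
    database = build_marker_database()
    tables: dict[str, pd.DataFrame] = {}
    truths = []
    for sample_id, mix in mixtures.iterrows():
        hits, truth = simulate_sample_hits(sample_id, mix.to_numpy(), database, params)
        tables[sample_id] = hits
        truth.insert(0, "sample_id", sample_id)
        truths.append(truth)
    return tables, pd.concat(truths, ignore_index=True), database


# ---------------------------------------------------------------------------
# trait matrix
# ---------------------------------------------------------------------------


def simulate_trait_matrix(
    n_clades: int = N_CLADES,
    n_traits: int = len(TRAIT_CATEGORIES),
    seed: int = 1,
    uniform: bool = False,
    concentration: float = 5.0,
) -> pd.DataFrame:
    """Random clade x trait-category proportion matrix (rows sum to 1).

    Stands in for trait relative abundances derived from annotated reference
    genomes; ``uniform=True`` gives the symmetric all-1/8 matrix.
    """
    if n_traits != len(TRAIT_CATEGORIES):
        raise ValueError(f"the trait framework has exactly {len(TRAIT_CATEGORIES)} categories")
    clades = MAIN_CLADES[:n_clades] if n_clades <= N_CLADES else tuple(
        str(i) for i in range(1, n_clades + 1)
    )
    if uniform:
        values = np.full((n_clades, n_traits), 1.0 / n_traits)
    else:
        rng = rng_for(seed, "traits")
        values = rng.dirichlet(np.full(n_traits, concentration), size=n_clades)
    return pd.DataFrame(values, index=list(clades), columns=list(TRAIT_CATEGORIES))


# ---------------------------------------------------------------------------
# writers (TSV boundary used by the CLI)
# ---------------------------------------------------------------------------


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def write_annotations(database: MarkerDatabase, path) -> None:
    database.to_frame().to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t")


def with_seed(params: ScenarioParams, seed: int) -> ScenarioParams:
    return replace(params, seed=seed)
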