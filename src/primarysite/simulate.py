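"""Labeled synthetic cohorts with the statistical structure the classifier assumes.

Each synthetic cancer type is an archetype: a small set of planted regional
mutational density profiles, a mixture over mutational-signature spectra,
Bernoulli prevalences for boolean driver/fusion/viral markers, Poisson rates
for structural-variant burden categories, planted chromosome-arm copy
numbers, and a gender constraint. Cohorts can be generated directly at the
feature level, or as raw per-sample input tables plus a toy reference genome
so that the whole extraction pipeline is exercised end to end.

The generator reuses the package's own encoders for everything derived from
structured records (SVs, events, copy number), so both modes produce the
same feature distributions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from primarysite.features.contexts import SCHEMES
from primarysite.features.copynumber import (
    build_arm_table,
    compute_arm_copy_number,
    compute_genome_properties,
)
from primarysite.features.extract import FeatureCatalog
from primarysite.features.matrix import FeatureMatrix, assemble_feature_matrix
from primarysite.features.records import (
    CNSegment,
    EventRecord,
    MutationRecord,
    SampleInputs,
    SampleMeta,
    SVClusterRecord,
)
from primarysite.features.rmd import build_bin_table, rmd_bin_feature_names
from primarysite.features.signatures import fit_signature_exposures, synthetic_catalog
from primarysite.features.sv_events import (
    encode_fusion_and_viral_features,
    encode_driver_features,
    encode_sv_features,
)

# Toy genome layout: five contigs (four autosomes and X), desk-scale bins.
TOY_CHROM_SIZES: Mapping[str, int] = {
    "1": 140_000, "2": 120_000, "3": 100_000, "4": 80_000, "X": 60_000,
}
TOY_CENTROMERES: Mapping[str, int] = {
    "1": 70_000, "2": 60_000, "3": 50_000, "4": 40_000, "X": 30_000,
}
TOY_BIN_SIZE = 10_000

#: SV cluster length/size sampling ranges per rate key.
_SV_LENGTH_RANGES = {
    "1e3_1e4": (1_000, 10_000), "1e4_1e5": (10_000, 100_000),
    "1e5_1e6": (100_000, 1_000_000), "1e6_1e7": (1_000_000, 10_000_000),
    "1e7_Inf": (10_000_000, 50_000_000),
}
_SV_SIZE_RANGES = {
    "0_25": (2, 25), "25_50": (25, 50), "50_100": (50, 100),
    "100_200": (100, 200), "200_400": (200, 400), "400_800": (400, 800),
    "800_Inf": (800, 1200),
}


@dataclass
class ClassArchetype:
    """Generating parameters of one synthetic cancer type."""

    name: str
    n_samples: int = 150
    gender: str = "any"  # "any" | "male_only" | "female_only"
    rmd_profiles: np.ndarray | None = None  # (k, n_bins), rows sum to 1
    rmd_alpha: float = 5.0  # Dirichlet concentration over the class profiles
    sbs_load_mean: float = 2000.0
    dbs_load_mean: float = 30.0
    indel_load_mean: float = 150.0
    signature_mix: Mapping[str, float] = field(default_factory=dict)  # SBS sigs
    bool_prevalence: Mapping[str, float] = field(default_factory=dict)
    sv_rates: Mapping[str, float] = field(default_factory=dict)
    arm_cn: Mapping[str, int] = field(default_factory=dict)
    genome_cn: int = 2

    def validate(self, n_bins: int, sig_names: Sequence[str]) -> list[str]:
        problems = []
        if self.n_samples < 1:
            problems.append(f"{self.name}: n_samples must be >= 1")
        if self.gender not in ("any", "male_only", "female_only"):
            problems.append(f"{self.name}: bad gender constraint {self.gender!r}")
        if self.rmd_profiles is not None:
            P = np.asarray(self.rmd_profiles)
            if P.ndim != 2 or P.shape[1] != n_bins:
                problems.append(f"{self.name}: rmd_profiles must be (k, {n_bins})")
            elif (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0):
                problems.append(f"{self.name}: rmd_profiles rows must be distributions")
        for feat, p in self.bool_prevalence.items():
            if not 0 <= p <= 1:
                problems.append(f"{self.name}: prevalence of {feat} not in [0,1]")
        for sig in self.signature_mix:
            if sig not in sig_names:
                problems.append(f"{self.name}: unknown signature {sig}")
        for key in self.sv_rates:
            parts = key.split(".")
            if parts[0] in ("DEL", "DUP") and parts[1] not in _SV_LENGTH_RANGES:
                problems.append(f"{self.name}: bad SV length key {key}")
            elif parts[0] == "COMPLEX" and parts[1] not in _SV_SIZE_RANGES:
                problems.append(f"{self.name}: bad SV size key {key}")
            elif parts[0] not in ("DEL", "DUP", "COMPLEX", "LINE", "double_minutes"):
                problems.append(f"{self.name}: unknown SV rate key {key}")
        return problems


@dataclass
class SyntheticCohortConfig:
    """A full cohort description: archetypes plus the shared reference tables."""

    classes: list[ClassArchetype]
    bin_table: pd.DataFrame
    arm_table: pd.DataFrame
    signature_catalogs: Mapping[str, pd.DataFrame]
    gene_catalog: tuple[str, ...] = ()
    known_fusion_pairs: tuple[str, ...] = ()
    promiscuous_genes: tuple[str, ...] = ()
    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: dict(TOY_CHROM_SIZES))

    @property
    def n_bins(self) -> int:
        return len(self.bin_table)

    def feature_catalog(self) -> FeatureCatalog:
        return FeatureCatalog(
            bin_table=self.bin_table,
            arm_table=self.arm_table,
            signature_catalogs=self.signature_catalogs,
            gene_catalog=self.gene_catalog,
            known_fusion_pairs=self.known_fusion_pairs,
            promiscuous_genes=self.promiscuous_genes,
        )

    def validate(self) -> None:
        sig_names = list(self.signature_catalogs["SBS96"].columns)
        problems = []
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            problems.append("duplicate class names")
        for cls in self.classes:
            problems += cls.validate(self.n_bins, sig_names)
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))


def random_profiles(n_profiles: int, n_bins: int, rng, support: int = 8) -> np.ndarray:
    """Sparse random profiles: each concentrates on its own few bins."""
    P = np.zeros((n_profiles, n_bins))
    for i in range(n_profiles):
        bins = rng.choice(n_bins, size=min(support, n_bins), replace=False)
        P[i, bins] = rng.dirichlet(np.ones(len(bins)))
        P[i] = 0.9 * P[i] + 0.1 / n_bins  # small dense floor
    return P / P.sum(axis=1, keepdims=True)


def example_cohort_config(
    n_classes: int = 8,
    samples_per_class: int = 150,
    profiles_per_class: int = 2,
    archetype_seed: int = 7,
) -> SyntheticCohortConfig:
    """Eight-archetype default cohort mimicking well-known tumor-type motifs.

    Includes a male-only prostate-like class with a recurrent fusion, a
    female-only cervix-like class with frequent HPV insertion, a
    smoking-signature lung-like class, an HBV liver-like class, an
    IGH-fusion lymphoid-like class, and a complex-SV sarcoma-like class.
    The archetypes borrow motif names for readability; no biological
    fidelity is claimed.
    """
    rng = np.random.default_rng(archetype_seed)
    bin_table = build_bin_table(dict(TOY_CHROM_SIZES), TOY_BIN_SIZE)
    arm_table = build_arm_table(dict(TOY_CHROM_SIZES), dict(TOY_CENTROMERES))
    catalogs = {
        "SBS96": synthetic_catalog("SBS96", 8, seed=11),
        "DBS78": synthetic_catalog("DBS78", 4, seed=12),
        "ID83": synthetic_catalog("ID83", 4, seed=13),
    }
    sigs = list(catalogs["SBS96"].columns)
    n_bins = len(bin_table)

    gene_catalog = ("TP53", "APC", "GATA3", "SPOP", "VHL", "KRAS", "IGLL5", "RB1")
    known_pairs = ("TMPRSS2_ERG", "EML4_ALK", "KIAA1549_BRAF", "FUS_DDIT3")
    promiscuous = ("MYC", "RUNX1")

    def mix(**kwargs):
        base = {s: 1.0 for s in sigs}
        base.update({k: v for k, v in kwargs.items()})
        total = sum(base.values())
        return {k: v / total for k, v in base.items()}

    specs = [
        ClassArchetype(
            name="BreastLike", gender="female_only",
            signature_mix=mix(SBS1=6, SBS3=4),
            bool_prevalence={"gene.GATA3.monoallelic": 0.4, "gene.TP53.monoallelic": 0.3},
            sv_rates={"DUP.1e4_1e5": 4.0, "DEL.1e3_1e4": 2.0},
            arm_cn={"1q": 3},
        ),
        ClassArchetype(
            name="CervixLike", gender="female_only",
            signature_mix=mix(SBS2=8),
            bool_prevalence={"viral_ins.HPV": 0.85, "gene.KRAS.monoallelic": 0.1},
            sv_rates={"DEL.1e3_1e4": 1.0},
        ),
        ClassArchetype(
            name="ProstateLike", gender="male_only",
            signature_mix=mix(SBS1=5),
            bool_prevalence={"fusion.TMPRSS2_ERG": 0.45, "gene.SPOP.monoallelic": 0.25},
            sv_rates={"DEL.1e5_1e6": 3.0},
            arm_cn={"4q": 1},
        ),
        ClassArchetype(
            name="LungSmokingLike",
            signature_mix=mix(SBS4=10),
            sbs_load_mean=4000.0,
            bool_prevalence={"fusion.EML4_ALK": 0.06, "gene.TP53.biallelic": 0.5},
            sv_rates={"DEL.1e4_1e5": 2.0},
        ),
        ClassArchetype(
            name="LiverLike",
            signature_mix=mix(SBS5=6),
            bool_prevalence={"viral_ins.HBV": 0.5, "gene.TP53.monoallelic": 0.3},
            sv_rates={"DUP.1e5_1e6": 2.0},
            arm_cn={"2p": 3},
        ),
        ClassArchetype(
            name="LymphoidLike",
            signature_mix=mix(SBS6=6),
            sbs_load_mean=1200.0,
            bool_prevalence={"fusion.IGH": 0.6, "gene.IGLL5.deep_del": 0.35},
            sv_rates={"DEL.1e3_1e4": 0.5},
        ),
        ClassArchetype(
            name="ColorectalLike",
            signature_mix=mix(SBS1=4, SBS7a=3),
            sbs_load_mean=3000.0,
            bool_prevalence={"gene.APC.monoallelic": 0.75, "gene.KRAS.monoallelic": 0.4},
            sv_rates={"DUP.1e3_1e4": 1.5},
            arm_cn={"3q": 3},
        ),
        ClassArchetype(
            name="SarcomaLike",
            signature_mix=mix(SBS7b=5),
            bool_prevalence={"fusion.FUS_DDIT3": 0.3, "gene.RB1.deep_del": 0.3},
            sv_rates={"COMPLEX.100_200": 2.0, "COMPLEX.25_50": 1.5,
                      "double_minutes": 0.4},
            arm_cn={"1p": 4, "2q": 1},
        ),
    ][:n_classes]
    for cls in specs:
        cls.n_samples = samples_per_class
        cls.rmd_profiles = random_profiles(profiles_per_class, n_bins, rng)
    config = SyntheticCohortConfig(
        classes=specs,
        bin_table=bin_table,
        arm_table=arm_table,
        signature_catalogs=catalogs,
        gene_catalog=gene_catalog,
        known_fusion_pairs=known_pairs,
        promiscuous_genes=promiscuous,
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# Drawing structured records per sample


def _draw_gender(cls: ClassArchetype, rng) -> str:
    if cls.gender == "male_only":
        return "male"
    if cls.gender == "female_only":
        return "female"
    return "male" if rng.random() < 0.5 else "female"


def _draw_cn_segments(
    cls: ClassArchetype, gender: str, config: SyntheticCohortConfig, rng
) -> list[CNSegment]:
    segments = []
    for row in config.arm_table.itertuples(index=False):
        chrom = row.chrom
        if chrom == "X" or chrom.lower() == "chrx":
            cn = (2 if gender == "female" else 1) * cls.genome_cn / 2
        else:
            cn = float(cls.arm_cn.get(row.arm, cls.genome_cn))
        jitter = rng.normal(0, 0.05)
        segments.append(
            CNSegment(chrom, int(row.start) + 1, int(row.end), max(0.0, cn + jitter))
        )
    return segments


def _draw_sv_clusters(cls: ClassArchetype, rng) -> list[SVClusterRecord]:
    clusters = []
    i = 0
    for key, rate in cls.sv_rates.items():
        parts = key.split(".")
        for _ in range(rng.poisson(rate)):
            i += 1
            if parts[0] in ("DEL", "DUP"):
                lo, hi = _SV_LENGTH_RANGES[parts[1]]
                clusters.append(
                    SVClusterRecord(
                        f"cl{i}", parts[0], n_sv=1, n_breakends=2,
                        length_bp=int(rng.integers(lo, hi)),
                    )
                )
            elif parts[0] == "COMPLEX":
                lo, hi = _SV_SIZE_RANGES[parts[1]]
                n_sv = int(rng.integers(lo, hi))
                clusters.append(
                    SVClusterRecord(
                        f"cl{i}", "COMPLEX", n_sv=n_sv,
                        n_breakends=int(n_sv * 2 + rng.integers(0, 5)),
                    )
                )
            elif parts[0] == "LINE":
                clusters.append(SVClusterRecord(f"cl{i}", "LINE", 1, 2))
            elif parts[0] == "double_minutes":
                clusters.append(SVClusterRecord(f"cl{i}", "DOUBLE_MINUTE", 1, 2))
    return clusters


def _draw_events(cls: ClassArchetype, rng) -> list[EventRecord]:
    events = []
    for feat, prevalence in cls.bool_prevalence.items():
        if rng.random() >= prevalence:
            continue
        ftype, rest = feat.split(".", 1)
        if ftype == "gene":
            gene, dtype = rest.rsplit(".", 1)
            likelihood = 0.95 if dtype == "monoallelic" else None
            events.append(EventRecord("driver", gene, dtype, likelihood))
        elif ftype == "fusion":
            events.append(EventRecord("fusion", rest))
        elif ftype == "viral_ins":
            events.append(EventRecord("viral", rest))
        else:
            raise ValueError(f"boolean prevalence for unsupported feature {feat}")
    return events


def _draw_loads(cls: ClassArchetype, rng) -> dict[str, int]:
    return {
        "snv": int(rng.poisson(cls.sbs_load_mean)),
        "dbs": int(rng.poisson(cls.dbs_load_mean)),
        "indel": int(rng.poisson(cls.indel_load_mean)),
    }


def _draw_rmd_weights(cls: ClassArchetype, rng) -> np.ndarray:
    k = cls.rmd_profiles.shape[0]
    if k == 1:
        return np.ones(1)
    return rng.dirichlet(np.full(k, cls.rmd_alpha))


def _sample_context_counts(
    mix: Mapping[str, float], catalog: pd.DataFrame, n: int, rng
) -> pd.Series:
    spectrum = np.zeros(catalog.shape[0])
    if mix:
        for sig, w in mix.items():
            spectrum += w * catalog[sig].to_numpy()
    else:
        spectrum = catalog.to_numpy().mean(axis=1)
    spectrum = spectrum / spectrum.sum()
    return pd.Series(rng.multinomial(n, spectrum), index=catalog.index)


# ---------------------------------------------------------------------------
# Feature-level generation


def generate_feature_cohort(
    config: SyntheticCohortConfig, seed: int = 0
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Generate a cohort directly at the feature level.

    RMD bins are multinomial draws from each sample's planted profile
    mixture (then normalized); signature features come from fitting
    multinomial context draws to the catalogs; boolean, SV and copy-number
    features are encoded from drawn records with the production encoders.
    Fully deterministic given (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    catalog = config.feature_catalog()
    bin_names = rmd_bin_feature_names(config.bin_table)
    vectors: dict[str, pd.Series] = {}
    truth_rows = []
    for cls in config.classes:
        for i in range(cls.n_samples):
            sid = f"{cls.name}_s{i:04d}"
            gender = _draw_gender(cls, rng)
            loads = _draw_loads(cls, rng)
            parts = []
            # signatures from multinomial context draws
            for scheme, prefix, mix in (
                ("SBS96", "snv", cls.signature_mix),
                ("DBS78", "dbs", {}),
                ("ID83", "indel", {}),
            ):
                sig_catalog = config.signature_catalogs[scheme]
                counts = _sample_context_counts(
                    mix, sig_catalog, loads[prefix], rng
                )
                _, normalized = fit_signature_exposures(counts, sig_catalog)
                normalized.index = [f"sigs.{n}" for n in normalized.index]
                parts.append(normalized)
            parts.append(
                pd.Series({f"mut_load.{k}": float(v) for k, v in loads.items()})
            )
            # RMD bins: multinomial from the profile mixture
            weights = _draw_rmd_weights(cls, rng)
            profile = weights @ cls.rmd_profiles
            draws = rng.multinomial(loads["snv"], profile)
            total = draws.sum()
            rmd = draws / total if total > 0 else draws.astype(float)
            parts.append(pd.Series(rmd, index=bin_names))
            # copy number
            segments = _draw_cn_segments(cls, gender, config, rng)
            arm = compute_arm_copy_number(segments, config.arm_table)
            parts.append(
                pd.Series({f"chrom_arm.{a}": v for a, v in arm.fold_change.items()})
            )
            props = compute_genome_properties(
                segments, SampleMeta(sid, gender, 1.0)
            )
            parts.append(
                pd.Series(
                    {
                        "genome.ploidy": props["genome_ploidy"],
                        "genome.diploid_proportion": props["diploid_proportion"],
                        "genome.wgd": float(props["wgd_flag"]),
                    }
                )
            )
            parts.append(pd.Series({"gender.male": 1.0 if gender == "male" else 0.0}))
            # SVs and events via the production encoders
            parts.append(encode_sv_features(_draw_sv_clusters(cls, rng)))
            events = _draw_events(cls, rng)
            parts.append(encode_driver_features(events, config.gene_catalog))
            parts.append(
                encode_fusion_and_viral_features(
                    events, config.known_fusion_pairs, config.promiscuous_genes
                )
            )
            vectors[sid] = pd.concat(parts)
            truth_rows.append((sid, cls.name, gender))
    matrix = assemble_feature_matrix(vectors)
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "class", "gender"]
    ).set_index("sample_id")
    return matrix, truth


# ---------------------------------------------------------------------------
# Raw-input generation


def make_toy_genome(
    chrom_sizes: Mapping[str, int] | None = None, seed: int = 101
) -> dict[str, str]:
    """A random reference genome with near-uniform base composition."""
    if chrom_sizes is None:
        chrom_sizes = TOY_CHROM_SIZES
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        chrom: "".join(bases[rng.integers(0, 4, size=size)])
        for chrom, size in chrom_sizes.items()
    }


def _index_trinucleotides(
    genome: Mapping[str, str], bin_table: pd.DataFrame
) -> list[dict[str, np.ndarray]]:
    """Per bin: canonical (pyrimidine-center) trinucleotide -> 0-based positions."""
    from primarysite.features.contexts import revcomp

    index: list[dict[str, np.ndarray]] = []
    for row in bin_table.itertuples(index=False):
        seq = genome[row.chrom][max(0, row.start - 1) : row.end + 1]
        offset = max(0, row.start - 1)
        buckets: dict[str, list[int]] = {}
        for i in range(1, len(seq) - 1):
            pos0 = offset + i
            if pos0 < row.start or pos0 >= row.end:
                continue
            tri = seq[i - 1 : i + 2]
            if tri[1] in "AG":
                tri = revcomp(tri)
            buckets.setdefault(tri, []).append(pos0)
        index.append({t: np.array(p) for t, p in buckets.items()})
    return index


def _place_sbs(
    context: str,
    bin_idx: int,
    tri_index,
    genome: Mapping[str, str],
    bin_table: pd.DataFrame,
    used: set,
    rng,
) -> MutationRecord | None:
    """Place one SBS of a given SBS96 category inside a given bin."""
    from primarysite.features.contexts import revcomp

    five, mid, three = context[0], context[2:5], context[6]
    ref, alt = mid[0], mid[2]
    tri = five + ref + three
    positions = tri_index[bin_idx].get(tri)
    if positions is None or len(positions) == 0:
        return None
    row = bin_table.iloc[bin_idx]
    for _ in range(10):
        pos0 = int(positions[rng.integers(0, len(positions))])
        if (row.chrom, pos0) not in used:
            break
    else:
        return None
    used.add((row.chrom, pos0))
    genome_base = genome[row.chrom][pos0]
    if genome_base == ref:
        return MutationRecord(row.chrom, pos0 + 1, ref, alt)
    # genome carries the purine strand: emit the complementary substitution
    return MutationRecord(row.chrom, pos0 + 1, revcomp(ref), revcomp(alt))


def generate_raw_inputs(
    config: SyntheticCohortConfig,
    seed: int = 0,
    genome: Mapping[str, str] | None = None,
) -> tuple[dict[str, SampleInputs], dict[str, str], pd.DataFrame]:
    """Generate per-sample raw inputs on a toy genome.

    SBS positions follow each sample's planted profile mixture over the bin
    table, and SBS contexts follow the planted signature mixture, so running
    feature extraction on the output recovers the planted structure.
    Returns (cohort, genome, truth).
    """
    config.validate()
    if genome is None:
        genome = make_toy_genome(config.chrom_sizes)
    for cls in config.classes:
        if cls.sbs_load_mean > 0.5 * sum(config.chrom_sizes.values()):
            raise ValueError(
                f"toy genome too small for mutation load of class {cls.name}"
            )
    rng = np.random.default_rng(seed)
    tri_index = _index_trinucleotides(genome, config.bin_table)
    sbs_catalog = config.signature_catalogs["SBS96"]
    cohort: dict[str, SampleInputs] = {}
    truth_rows = []
    chroms = list(config.chrom_sizes)
    for cls in config.classes:
        for i in range(cls.n_samples):
            sid = f"{cls.name}_s{i:04d}"
            gender = _draw_gender(cls, rng)
            loads = _draw_loads(cls, rng)
            used: set = set()
            mutations: list[MutationRecord] = []
            weights = _draw_rmd_weights(cls, rng)
            profile = weights @ cls.rmd_profiles
            bin_draws = rng.multinomial(loads["snv"], profile)
            context_counts = _sample_context_counts(
                cls.signature_mix, sbs_catalog, loads["snv"], rng
            )
            contexts = np.repeat(
                context_counts.index.to_numpy(), context_counts.to_numpy()
            )
            rng.shuffle(contexts)
            ci = 0
            for bin_idx, n_in_bin in enumerate(bin_draws):
                for _ in range(n_in_bin):
                    mut = _place_sbs(
                        contexts[ci % len(contexts)] if len(contexts) else "A[C>T]A",
                        bin_idx, tri_index, genome, config.bin_table, used, rng,
                    )
                    ci += 1
                    if mut is not None:
                        mutations.append(mut)
            mutations += _random_dbs(genome, chroms, config, loads["dbs"], used, rng)
            mutations += _random_indels(genome, chroms, config, loads["indel"], used, rng)
            meta = SampleMeta(sid, gender, float(rng.uniform(0.6, 1.0)))
            cohort[sid] = SampleInputs(
                meta=meta,
                mutations=mutations,
                cn_segments=_draw_cn_segments(cls, gender, config, rng),
                sv_clusters=_draw_sv_clusters(cls, rng),
                events=_draw_events(cls, rng),
            )
            truth_rows.append((sid, cls.name, gender))
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "class", "gender"]
    ).set_index("sample_id")
    return cohort, dict(genome), truth


def _random_dbs(genome, chroms, config, n, used, rng) -> list[MutationRecord]:
    out = []
    for _ in range(n):
        for _ in range(20):
            chrom = chroms[rng.integers(0, len(chroms))]
            size = config.chrom_sizes[chrom]
            pos0 = int(rng.integers(1, size - 2))
            if (chrom, pos0) in used or (chrom, pos0 + 1) in used:
                continue
            ref = genome[chrom][pos0 : pos0 + 2]
            alt = "".join(
                "ACGT".replace(b, "")[rng.integers(0, 3)] for b in ref
            )
            used.add((chrom, pos0))
            used.add((chrom, pos0 + 1))
            out.append(MutationRecord(chrom, pos0 + 1, ref, alt))
            break
    return out


def _random_indels(genome, chroms, config, n, used, rng) -> list[MutationRecord]:
    out = []
    for _ in range(n):
        for _ in range(20):
            chrom = chroms[rng.integers(0, len(chroms))]
            size = config.chrom_sizes[chrom]
            pos0 = int(rng.integers(1, size - 10))
            if (chrom, pos0) in used:
                continue
            anchor = genome[chrom][pos0]
            used.add((chrom, pos0))
            if rng.random() < 0.5:  # 1 bp deletion
                deleted = genome[chrom][pos0 + 1]
                out.append(
                    MutationRecord(chrom, pos0 + 1, anchor + deleted, anchor)
                )
            else:  # 1 bp insertion
                inserted = "ACGT"[rng.integers(0, 4)]
                out.append(MutationRecord(chrom, pos0 + 1, anchor, anchor + inserted))
            break
    return out


def write_raw_inputs(
    cohort: Mapping[str, SampleInputs],
    genome: Mapping[str, str],
    config: SyntheticCohortConfig,
    truth: pd.DataFrame,
    outdir,
) -> None:
    """Write a raw-input file tree (FASTA, per-sample TSVs, bins, truth)."""
    from primarysite.features import io as fio
    from primarysite.features.rmd import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_fasta(dict(genome), outdir / "reference.fa")
    write_bed(config.bin_table, outdir / "rmd_bins.bed")
    config.arm_table.to_csv(outdir / "arms.tsv", sep="\t", index=False)
    fio.write_sample_meta_tsv(
        [inp.meta for inp in cohort.values()], outdir / "sample_meta.tsv"
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    for scheme, cat in config.signature_catalogs.items():
        cat.to_csv(outdir / f"signatures_{scheme}.tsv", sep="\t", index_label="context")
    samples_dir = outdir / "samples"
    samples_dir.mkdir(exist_ok=True)
    for sid, inp in cohort.items():
        d = samples_dir / sid
        d.mkdir(exist_ok=True)
        fio.write_mutations_tsv(inp.mutations, d / "mutations.tsv")
        fio.write_cn_segments_tsv(inp.cn_segments, d / "cn_segments.tsv")
        fio.write_sv_clusters_tsv(inp.sv_clusters, d / "sv_clusters.tsv")
        fio.write_events_tsv(inp.events, d / "events.tsv")
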