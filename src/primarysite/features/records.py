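"""Domain record types for somatic variant, copy-number, SV and event inputs."""

from __future__ import annotations

from dataclasses import dataclass, field

_VALID_BASES = frozenset("ACGT")

SV_TYPES = ("DEL", "DUP", "COMPLEX", "LINE", "DOUBLE_MINUTE", "OTHER")
DRIVER_TYPES = ("amp", "deep_del", "biallelic", "monoallelic")
EVENT_KINDS = ("driver", "fusion", "viral")
GENDERS = ("male", "female", "unknown")


@dataclass(frozen=True)
class MutationRecord:
    """A somatic small variant: SNV, MNV or indel in VCF-like representation.

    ``pos`` is 1-based. For indels, ``ref`` and ``alt`` share a leading
    anchor base, as in VCF (e.g. ref="AC", alt="A" deletes the C).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_mnv(self) -> bool:
        return len(self.ref) == len(self.alt) > 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class CNSegment:
    """Somatic total copy-number segment; 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end ({self.start} > {self.end})")
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SVClusterRecord:
    """A structural-variant cluster with a resolved event type.

    ``length_bp`` is required for simple DEL/DUP clusters and absent otherwise.
    """

    cluster_id: str
    resolved_type: str
    n_sv: int = 1
    n_breakends: int = 2
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.resolved_type in ("DEL", "DUP") and self.length_bp is None:
            raise ValueError(f"{self.resolved_type} cluster {self.cluster_id} lacks length_bp")
        if self.length_bp is not None and self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.n_sv < 1 or self.n_breakends < self.n_sv:
            raise ValueError("need n_breakends >= n_sv >= 1")


@dataclass(frozen=True)
class EventRecord:
    """A driver, fusion or viral-insertion event.

    For drivers, ``name`` is a gene symbol and ``driver_type`` one of
    ``amp | deep_del | biallelic | monoallelic`` (monoallelic events carry a
    ``driver_likelihood``). For fusions, ``name`` is "GENE5_GENE3" or "IGH".
    For viral insertions, ``name`` is the virus strain description.
    """

    kind: str
    name: str
    driver_type: str | None = None
    driver_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "driver":
            if self.driver_type not in DRIVER_TYPES:
                raise ValueError(f"driver event needs driver_type in {DRIVER_TYPES}")
            if self.driver_type == "monoallelic" and self.driver_likelihood is None:
                raise ValueError("monoallelic driver events need driver_likelihood")
        if self.driver_likelihood is not None and not 0 <= self.driver_likelihood <= 1:
            raise ValueError("driver_likelihood must be in [0, 1]")


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata used for inclusion filters and the gender filter."""

    sample_id: str
    gender: str = "unknown"
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not 0 <= self.purity <= 1:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")


@dataclass
class SampleInputs:
    """All raw inputs for one sample, bundled for feature extraction."""

    meta: SampleMeta
    mutations: list = field(default_factory=list)
    cn_segments: list = field(default_factory=list)
    sv_clusters: list = field(default_factory=list)
    events: list = field(default_factory=list)
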