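"""Synthetic genome-ordered copy-number / expression datasets with survival.

The generator emulates the structure of a myeloma-style SNP-array cohort:
a markers x samples copy-number matrix in genome order, planted focal
alterations (deletion to 1 copy or gain to 3 copies) carried by a fixed
fraction of samples, Gaussian measurement noise on the copy scale, and
exponential survival whose hazard is multiplied by exp(beta) for carriers
of each altered region.  Censoring is independent uniform(0, C).  The
exponential baseline keeps everything checkable in closed form: the median
event time of a group with hazard ratio HR is ln 2 / (lambda0 * HR), and
the censored fraction under the null is (1 - exp(-lambda0 C)) / (lambda0 C).

Optionally an expression matrix with planted sample clusters is produced
for the clustering / K-M workflow (log-normal signal, a signature gene set
shifted between groups, optional per-group hazard effect).

Everything is deterministic given the spec's seed, and the writers reuse
the package's tab-delimited dialects byte-for-byte reproducibly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenomeMatrix, MarkerAnnotation, SampleTable

DELETION_COPIES = 1.0
GAIN_COPIES = 3.0


@dataclass(frozen=True)
class Region:
    """A planted copy-number alteration.

    ``start``/``end`` are 0-based inclusive marker indices within the
    chromosome; ``log_hr`` is the carrier's log hazard ratio.
    """

    chromosome: str
    start: int
    end: int
    alteration: str = "deletion"  # or "gain"
    carrier_fraction: float = 0.4
    log_hr: float = math.log(3.0)

    def __post_init__(self) -> None:
        if self.alteration not in ("deletion", "gain"):
            raise ValueError("alteration must be 'deletion' or 'gain'")
        if not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier fraction must be in (0, 1)")
        if self.end < self.start or self.start < 0:
            raise ValueError("invalid region bounds")

    @property
    def copies(self) -> float:
        return DELETION_COPIES if self.alteration == "deletion" else GAIN_COPIES


@dataclass(frozen=True)
class ClusterSpec:
    """Planted expression clusters: groups differ on a signature gene set."""

    n_groups: int = 2
    n_genes: int = 500
    n_signature: int = 100
    shift: float = 1.0        # log-scale separation between adjacent groups
    log_hr: float = 0.0       # per-group-index hazard effect
    noise_sd: float = 0.4     # log-scale per-cell noise


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic study.

    Defaults are the "demo" conditions: 200 samples, 2,000 markers over 4
    chromosomes, one 50-marker deletion region carried by 40% of samples
    with hazard ratio 3, baseline chosen so the null median survival is 36
    time units (lambda0 = ln 2 / 36), uniform(0, 120) censoring, copy noise
    sd 0.35.
    """

    n_samples: int = 200
    chromosomes: tuple[tuple[str, int], ...] = (
        ("1", 500),
        ("2", 500),
        ("3", 500),
        ("4", 500),
    )
    regions: tuple[Region, ...] = (
        Region("1", 100, 149, "deletion", 0.4, math.log(3.0)),
    )
    cn_noise_sd: float = 0.35
    baseline_rate: float = math.log(2.0) / 36.0
    censor_max: float = 120.0
    marker_spacing: int = 100_000
    cluster_spec: ClusterSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if self.n_samples < 1 or not self.chromosomes:
            raise ValueError("need at least one sample and one chromosome")
        sizes = dict(self.chromosomes)
        for r in self.regions:
            if r.chromosome not in sizes:
                raise ValueError(f"region on unknown chromosome {r.chromosome!r}")
            if r.end >= sizes[r.chromosome]:
                raise ValueError(f"region {r} exceeds chromosome bounds")

    @property
    def n_markers(self) -> int:
        return sum(n for _, n in self.chromosomes)


def demo_spec(seed: int = 0) -> SimulationSpec:
    """The default planted-deletion demonstration study."""
    return SimulationSpec(seed=seed)


def null_spec(seed: int = 0, n_samples: int = 100, n_markers: int = 500) -> SimulationSpec:
    """A global-null study: no planted regions, copy number pure noise."""
    half = n_markers // 2
    return SimulationSpec(
        n_samples=n_samples,
        chromosomes=(("1", half), ("2", n_markers - half)),
        regions=(),
        seed=seed,
    )


@dataclass
class SimulatedDataset:
    """Everything one synthetic study produced, plus the planted truth."""

    spec: SimulationSpec
    matrix: GenomeMatrix
    annotation: MarkerAnnotation
    sample_table: SampleTable
    carriers: dict[int, np.ndarray]      # region index -> bool per sample
    expression: GenomeMatrix | None = None
    cluster_groups: np.ndarray | None = None

    @property
    def survival(self):
        return self.sample_table.survival_data()

    def region_interval(self, i: int = 0) -> tuple[str, int, int]:
        """Planted region i as (chromosome, start position, end position)."""
        r = self.spec.regions[i]
        ann = self.annotation.table
        on = ann["chromosome"] == r.chromosome
        pos = ann.loc[on, "position"].to_numpy()
        return r.chromosome, int(pos[r.start]), int(pos[r.end])


def _make_annotation(spec: SimulationSpec) -> MarkerAnnotation:
    rows = []
    for chrom, n in spec.chromosomes:
        for i in range(n):
            rows.append(
                {
                    "marker_id": f"SNP_{chrom}_{i + 1:05d}",
                    "chromosome": chrom,
                    "position": (i + 1) * spec.marker_spacing,
                }
            )
    return MarkerAnnotation(pd.DataFrame(rows))


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one dataset from the spec; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    S = spec.n_samples
    annotation = _make_annotation(spec)
    M = annotation.n_markers
    sample_ids = [f"S{i + 1:03d}" for i in range(S)]

    chrom_start = {}
    offset = 0
    for chrom, n in spec.chromosomes:
        chrom_start[chrom] = offset
        offset += n

    # planted alterations: exact carrier counts, drawn without replacement
    true_copies = np.full((M, S), 2.0)
    carriers: dict[int, np.ndarray] = {}
    log_hr = np.zeros(S)
    for i, region in enumerate(spec.regions):
        n_carr = int(round(region.carrier_fraction * S))
        idx = rng.choice(S, size=n_carr, replace=False)
        carr = np.zeros(S, dtype=bool)
        carr[idx] = True
        carriers[i] = carr
        lo = chrom_start[region.chromosome] + region.start
        hi = chrom_start[region.chromosome] + region.end + 1
        true_copies[lo:hi, carr] = region.copies
        log_hr += region.log_hr * carr

    values = true_copies + rng.normal(0.0, spec.cn_noise_sd, size=(M, S))
    np.clip(values, 0.0, None, out=values)
    matrix = GenomeMatrix(values, annotation, sample_ids)

    # expression clusters decided before survival so they can shape the hazard
    expression = None
    groups = None
    if spec.cluster_spec is not None:
        cs = spec.cluster_spec
        groups = rng.integers(0, cs.n_groups, size=S)
        baseline = rng.lognormal(mean=math.log(100.0), sigma=0.6, size=cs.n_genes)
        expr = baseline[:, None] * np.exp(
            rng.normal(0.0, cs.noise_sd, size=(cs.n_genes, S))
        )
        centred = groups - (cs.n_groups - 1) / 2.0
        expr[: cs.n_signature] *= np.exp(cs.shift * centred)[None, :]
        gene_ann = MarkerAnnotation(
            pd.DataFrame(
                {
                    "marker_id": [f"GENE_{i + 1:04d}" for i in range(cs.n_genes)],
                    "chromosome": ["1"] * cs.n_genes,
                    "position": np.arange(1, cs.n_genes + 1) * 1000,
                }
            )
        )
        expression = GenomeMatrix(expr, gene_ann, sample_ids)
        log_hr = log_hr + cs.log_hr * groups

    rate = spec.baseline_rate * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0.0, spec.censor_max, size=S)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(float)

    data = pd.DataFrame(index=pd.Index(sample_ids, name="Sample"))
    data["Survival(numeric)"] = np.round(time, 6)
    data["Event(numeric)"] = event
    for i, carr in carriers.items():
        data[f"Carrier{i + 1}(numeric)"] = carr.astype(float)
    if groups is not None:
        data["Cluster(numeric)"] = groups.astype(float)
    table = SampleTable(data=data)

    return SimulatedDataset(
        spec=spec,
        matrix=matrix,
        annotation=annotation,
        sample_table=table,
        carriers=carriers,
        expression=expression,
        cluster_groups=groups,
    )


def expected_censoring_fraction(spec: SimulationSpec) -> float:
    """Closed-form P(censor < event) for a non-carrier under the spec."""
    lc = spec.baseline_rate * spec.censor_max
    return (1.0 - math.exp(-lc)) / lc


def write_dataset(sim: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every dialect to ``outdir``; byte-identical for equal seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "cn_matrix.txt",
        "annotation": outdir / "annotation.txt",
        "sample_info": outdir / "sample_info.txt",
        "spec": outdir / "spec.json",
    }
    sim.matrix.write(paths["matrix"])
    sim.annotation.write(paths["annotation"])
    sim.sample_table.write(paths["sample_info"])
    if sim.expression is not None:
        paths["expression"] = outdir / "expression.txt"
        sim.expression.write(paths["expression"])
    paths["spec"].write_text(spec_to_json(sim.spec), encoding="utf-8")
    return paths


def spec_to_json(spec: SimulationSpec) -> str:
    d = asdict(spec)
    d["chromosomes"] = [list(c) for c in spec.chromosomes]
    return json.dumps(d, indent=2, sort_keys=True) + "\n"


def spec_from_json(text: str) -> SimulationSpec:
    d = json.loads(text)
    d["chromosomes"] = tuple((str(c), int(n)) for c, n in d["chromosomes"])
    d["regions"] = tuple(Region(**r) for r in d.get("regions", ()))
    if d.get("cluster_spec"):
        d["cluster_spec"] = ClusterSpec(**d["cluster_spec"])
    return SimulationSpec(**d)
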