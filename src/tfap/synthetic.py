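"""Ground-truth cohort simulation for end-to-end pipeline testing.

Generates latent per-group TF activities with a known driver set,
reporter construct batteries (at most six constructs per animal),
TF-weighted log-linear gene expression, SI-rate behavior coupled to
driver activity, promoter sequences with implanted binding sites, and
qPCR standard-curve readouts. One root seed fans out to independent
per-component child streams via ``numpy.random.SeedSequence.spawn``
(spawn order: truth, reporters, expression, behavior, promoters,
qpcr, motifs), so every generator is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tfap._errors import ConfigError
from tfap.quantify import (
    QpcrStandardSeries,
    StandardCurve,
    simulate_standard_series,
)
from tfap.regulon import Motif, PromoterRecord, reverse_complement

MAX_BATTERY_SIZE = 6

_SPAWN_ORDER = (
    "truth",
    "reporters",
    "expression",
    "behavior",
    "promoters",
    "qpcr",
    "motifs",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``groups[0]`` is the control group; drivers carry
    ``effect_log2fc`` in every non-control group.
    """

    n_tfs: int = 30
    n_genes: int = 1000
    n_animals_per_group: int = 10
    n_drivers: int = 2
    battery_size: int = 6
    regulon_size: int = 30
    effect_log2fc: float = 0.5
    regulon_weight: float = 1.0
    groups: tuple[str, ...] = ("control", "susceptible")
    noise_sd_reporter: float = 0.0
    noise_sd_expr: float = 0.0
    noise_sd_behavior: float = 0.0
    behavior_coupling: float = -1.0
    si_baseline: float = 1.5
    base_zone_time_s: float = 50.0
    days: tuple[int, ...] = (1,)
    baseline_expr_range: tuple[float, float] = (5.0, 9.0)
    gene_length_bp: int = 1000
    reference_copies: float = 1e4
    integer_counts: bool = True
    promoter_upstream: int = 250
    promoter_downstream: int = 50
    motif_length: int = 8
    motif_dominant_prob: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.battery_size <= MAX_BATTERY_SIZE:
            raise ConfigError(
                f"battery_size must be in [1, {MAX_BATTERY_SIZE}], "
                f"got {self.battery_size}"
            )
        for name in ("n_tfs", "n_genes", "n_animals_per_group"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_drivers < 0 or self.n_drivers > self.n_tfs:
            raise ConfigError(
                f"n_drivers must be in [0, n_tfs={self.n_tfs}], "
                f"got {self.n_drivers}"
            )
        if self.regulon_size < 1 or self.regulon_size > self.n_genes:
            raise ConfigError("regulon_size must be in [1, n_genes]")
        for name in ("noise_sd_reporter", "noise_sd_expr", "noise_sd_behavior"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.groups) < 2:
            raise ConfigError("need a control group and >=1 other group")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("group names must be unique")

    @property
    def control_group(self) -> str:
        return self.groups[0]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:02d}" for i in range(self.n_tfs)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_genes)]

    def child_rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component generator (see module docstring)."""
        children = np.random.SeedSequence(self.seed).spawn(len(_SPAWN_ORDER))
        return np.random.default_rng(children[_SPAWN_ORDER.index(component)])


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent ground truth behind one simulated cohort."""

    tf_ids: tuple[str, ...]
    driver_set: tuple[str, ...]
    activity_log2fc: pd.DataFrame  # TF x group, log2 units; control column 0
    regulon_weights: pd.DataFrame  # TF x gene; 0 == non-target
    baseline_expr: pd.Series  # per-gene baseline log2 abundance
    behavior_coupling: dict[str, float]  # per-driver SI coefficient
    seed: int

    def true_regulon(self, tf_id: str) -> set[str]:
        row = self.regulon_weights.loc[tf_id]
        return set(row.index[row != 0.0])

    def validate(self) -> None:
        assert set(self.driver_set) <= set(self.tf_ids)
        non_drivers = [t for t in self.tf_ids if t not in self.driver_set]
        assert (self.activity_log2fc.loc[non_drivers] == 0).all().all()
        control = self.activity_log2fc.columns[0]
        assert (self.activity_log2fc[control] == 0).all()


def make_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the latent truth: drivers, activities, regulons, baselines."""
    rng = config.child_rng("truth")
    tf_ids = config.tf_ids
    drivers = tuple(
        sorted(rng.choice(tf_ids, size=config.n_drivers, replace=False))
    )
    activity = pd.DataFrame(
        0.0, index=tf_ids, columns=list(config.groups)
    )
    for group in config.groups[1:]:
        activity.loc[list(drivers), group] = config.effect_log2fc
    weights = pd.DataFrame(0.0, index=tf_ids, columns=config.gene_ids)
    for tf in tf_ids:
        targets = rng.choice(
            config.gene_ids, size=config.regulon_size, replace=False
        )
        weights.loc[tf, targets] = config.regulon_weight
    lo, hi = config.baseline_expr_range
    baseline = pd.Series(
        rng.uniform(lo, hi, size=config.n_genes),
        index=config.gene_ids,
        name="baseline_log2",
    )
    coupling = {d: config.behavior_coupling for d in drivers}
    truth = SyntheticTruth(
        tf_ids=tuple(tf_ids),
        driver_set=drivers,
        activity_log2fc=activity,
        regulon_weights=weights,
        baseline_expr=baseline,
        behavior_coupling=coupling,
        seed=config.seed,
    )
    truth.validate()
    return truth


def battery_panels(config: SimulationConfig) -> list[list[str]]:
    """Fixed TF panels of at most ``battery_size`` constructs.

    Panels partition the TF list; animals cycle through panels so the
    whole battery is covered once the cohort has >= n_panels animals
    per group.
    """
    tfs = config.tf_ids
    return [
        tfs[i : i + config.battery_size]
        for i in range(0, len(tfs), config.battery_size)
    ]


def animal_ids(config: SimulationConfig, group: str) -> list[str]:
    return [
        f"{group}_{i:03d}" for i in range(config.n_animals_per_group)
    ]


def simulate_reporter_counts(
    truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Reporter/reference transcript copies per animal x construct.

    Each animal carries one panel (<= battery_size constructs);
    reporter copies = reference copies x 2**activity x multiplicative
    lognormal noise (log2-scale SD ``noise_sd_reporter``). The panel
    index doubles as the experiment id, so each experiment contains
    control animals for every TF it measures.
    """
    if list(truth.tf_ids) != config.tf_ids:
        raise ConfigError("truth and config disagree on TF identities")
    rng = config.child_rng("reporters")
    panels = battery_panels(config)
    rows = []
    for group in config.groups:
        for i, animal in enumerate(animal_ids(config, group)):
            panel_idx = i % len(panels)
            for tf in panels[panel_idx]:
                act = truth.activity_log2fc.loc[tf, group]
                ref_noise = (
                    2.0 ** rng.normal(0.0, config.noise_sd_reporter)
                    if config.noise_sd_reporter > 0
                    else 1.0
                )
                rep_noise = (
                    2.0 ** rng.normal(0.0, config.noise_sd_reporter)
                    if config.noise_sd_reporter > 0
                    else 1.0
                )
                reference = config.reference_copies * ref_noise
                reporter = config.reference_copies * (2.0**act) * rep_noise
                rows.append(
                    {
                        "animal_id": animal,
                        "experiment_id": f"exp{panel_idx:02d}",
                        "group": group,
                        "tf_id": tf,
                        "reporter_copies": reporter,
                        "reference_copies": reference,
                    }
                )
    return pd.DataFrame(rows)


def simulate_expression(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Counts matrix (genes x samples), gene lengths, sample -> group map.

    Per-gene log2 abundance = baseline + sum_t weight[t, g] *
    activity[t, group] + N(0, noise_sd_expr); abundances are rounded
    to integer counts unless ``config.integer_counts`` is off.
    """
    rng = config.child_rng("expression")
    genes = config.gene_ids
    columns: dict[str, np.ndarray] = {}
    sample_groups: dict[str, str] = {}
    w = truth.regulon_weights.to_numpy()  # (n_tfs, n_genes)
    base = truth.baseline_expr.to_numpy()
    for group in config.groups:
        act = truth.activity_log2fc[group].to_numpy()
        signal = base + act @ w
        for animal in animal_ids(config, group):
            noise = (
                rng.normal(0.0, config.noise_sd_expr, size=len(genes))
                if config.noise_sd_expr > 0
                else 0.0
            )
            abundance = 2.0 ** (signal + noise)
            if config.integer_counts:
                abundance = np.maximum(np.rint(abundance), 1.0)
            columns[animal] = abundance
            sample_groups[animal] = group
    expr = pd.DataFrame(columns, index=genes)
    lengths = pd.Series(
        float(config.gene_length_bp), index=genes, name="length_bp"
    )
    return expr, lengths, sample_groups


def simulate_behavior(
    truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Interaction-zone trial times whose SI-rate tracks driver activity.

    SI = si_baseline + sum_d coupling[d] * activity[d, group] +
    N(0, noise_sd_behavior), floored at 0. Times are back-computed as
    time_no_mouse = base_zone_time_s, time_with_mouse = SI x that.
    """
    rng = config.child_rng("behavior")
    rows = []
    for group in config.groups:
        drift = sum(
            coef * truth.activity_log2fc.loc[d, group]
            for d, coef in truth.behavior_coupling.items()
        )
        for animal in animal_ids(config, group):
            for day in config.days:
                noise = (
                    rng.normal(0.0, config.noise_sd_behavior)
                    if config.noise_sd_behavior > 0
                    else 0.0
                )
                si = max(0.0, config.si_baseline + drift + noise)
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "day": day,
                        "time_no_mouse": config.base_zone_time_s,
                        "time_with_mouse": si * config.base_zone_time_s,
                    }
                )
    return pd.DataFrame(rows)


def make_motifs(
    config: SimulationConfig, pseudocount: float = 0.01
) -> list[Motif]:
    """One sharp random motif per TF (dominant consensus base)."""
    rng = config.child_rng("motifs")
    out = []
    for tf in config.tf_ids:
        consensus = rng.integers(0, 4, size=config.motif_length)
        mat = np.full(
            (4, config.motif_length), (1.0 - config.motif_dominant_prob) / 3.0
        )
        mat[consensus, np.arange(config.motif_length)] = (
            config.motif_dominant_prob
        )
        out.append(Motif.from_counts(tf, mat, pseudocount))
    return out


@dataclass
class SimulatedPromoters:
    """Synthetic genome plus per-gene promoter records and implant log."""

    genome: dict[str, str]
    tss_bed: pd.DataFrame  # BED6 columns
    promoters: dict[str, PromoterRecord]
    implants: dict[str, list[tuple[str, int, str]]] = field(
        default_factory=dict
    )


def simulate_promoters(
    truth: SyntheticTruth,
    motif_list: Sequence[Motif],
    config: SimulationConfig,
) -> SimulatedPromoters:
    """Build a synthetic genome whose promoters carry implanted sites.

    Every true target's promoter gets the consensus of each TF that
    regulates it, implanted at a distinct slot on a random strand;
    background is i.i.d. uniform A/C/G/T. Genes alternate strands;
    minus-strand promoter segments are stored reverse-complemented in
    the genome so extraction recovers the gene-oriented sequence.
    """
    rng = config.child_rng("promoters")
    window = config.promoter_upstream + config.promoter_downstream
    by_tf = {m.tf_id: m for m in motif_list}
    missing = set(truth.tf_ids) - set(by_tf)
    if missing:
        raise ConfigError(f"motifs missing for TFs: {sorted(missing)[:5]}")
    max_len = max(m.length for m in motif_list)
    if max_len > window:
        raise ConfigError(
            f"motif length {max_len} exceeds promoter window {window}"
        )
    n_slots = window // max_len
    regulators: dict[str, list[str]] = {g: [] for g in config.gene_ids}
    for tf in truth.tf_ids:
        for gene in truth.true_regulon(tf):
            regulators[gene].append(tf)

    spacer = 20
    pieces: list[str] = []
    cursor = 0
    bed_rows = []
    promoters: dict[str, PromoterRecord] = {}
    implants: dict[str, list[tuple[str, int, str]]] = {}
    bases = np.array(list("ACGT"))
    for idx, gene in enumerate(config.gene_ids):
        tfs_here = regulators[gene]
        if len(tfs_here) > n_slots:
            raise ConfigError(
                f"gene {gene!r}: {len(tfs_here)} regulators exceed "
                f"{n_slots} implant slots"
            )
        seq = rng.choice(bases, size=window)
        slots = rng.choice(n_slots, size=len(tfs_here), replace=False)
        gene_implants = []
        for tf, slot in zip(tfs_here, slots):
            motif = by_tf[tf]
            offset = int(slot) * max_len
            site = motif.consensus
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                site = reverse_complement(site)
            seq[offset : offset + motif.length] = list(site)
            gene_implants.append((tf, offset, strand))
        promoter_seq = "".join(seq)
        strand = "+" if idx % 2 == 0 else "-"
        lead = "".join(rng.choice(bases, size=spacer))
        pieces.append(lead)
        cursor += spacer
        start = cursor
        if strand == "+":
            pieces.append(promoter_seq)
            tss = start + config.promoter_upstream
        else:
            pieces.append(reverse_complement(promoter_seq))
            tss = start + config.promoter_downstream - 1
        cursor += window
        bed_rows.append(
            {
                "contig": "chr1",
                "start": tss,
                "end": tss + 1,
                "name": gene,
                "score": 0,
                "strand": strand,
            }
        )
        promoters[gene] = PromoterRecord(
            gene=gene,
            sequence=promoter_seq,
            contig="chr1",
            start=start,
            end=start + window,
            strand=strand,
        )
        if gene_implants:
            implants[gene] = gene_implants
    pieces.append("".join(rng.choice(bases, size=spacer)))
    genome = {"chr1": "".join(pieces)}
    return SimulatedPromoters(
        genome=genome,
        tss_bed=pd.DataFrame(bed_rows),
        promoters=promoters,
        implants=implants,
    )


def make_standard_curves(
    config: SimulationConfig,
) -> tuple[dict[str, StandardCurve], dict[str, QpcrStandardSeries]]:
    """True standard curves and noiseless dilution series per amplicon.

    One curve per (TF, role) amplicon; slopes jitter around the
    perfect-efficiency value of -log2(10) cycles per decade.
    """
    rng = config.child_rng("qpcr")
    curves: dict[str, StandardCurve] = {}
    series: dict[str, QpcrStandardSeries] = {}
    dilution_copies = [10.0**k for k in range(2, 8)]
    for tf in config.tf_ids:
        for role in ("reporter", "reference"):
            target = f"{tf}_{role}"
            slope = -np.log2(10.0) * 10 ** rng.normal(0.0, 0.005)
            intercept = rng.uniform(38.0, 42.0)
            s = simulate_standard_series(
                slope, intercept, dilution_copies, 0.0, target_id=target
            )
            curves[target] = StandardCurve(
                target_id=target,
                slope=float(slope),
                intercept=float(intercept),
                efficiency=float(10.0 ** (-1.0 / slope) - 1.0),
                r_squared=1.0,
            )
            series[target] = s
    return curves, series


def simulate_qpcr(
    reporter_counts: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
    noise_sd_cq: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cq readouts for every construct under the true standard curves."""
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for row in reporter_counts.itertuples():
        for role, copies in (
            ("reporter", row.reporter_copies),
            ("reference", row.reference_copies),
        ):
            target = f"{row.tf_id}_{role}"
            curve = curves[target]
            cq = curve.intercept + curve.slope * np.log10(copies)
            if noise_sd_cq > 0:
                cq += rng.normal(0.0, noise_sd_cq)
            rows.append(
                {
                    "animal_id": row.animal_id,
                    "experiment_id": row.experiment_id,
                    "tf_id": row.tf_id,
                    "role": role,
                    "target_id": target,
                    "cq": cq,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization helpers


def truth_to_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "tf_ids": list(truth.tf_ids),
        "driver_set": list(truth.driver_set),
        "activity_log2fc": {
            g: truth.activity_log2fc[g].to_dict()
            for g in truth.activity_log2fc.columns
        },
        "regulons": {
            tf: sorted(truth.true_regulon(tf)) for tf in truth.tf_ids
        },
        "baseline_expr": truth.baseline_expr.to_dict(),
        "behavior_coupling": truth.behavior_coupling,
        "seed": truth.seed,
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def standards_to_frame(
    series: Mapping[str, QpcrStandardSeries]
) -> pd.DataFrame:
    rows = [
        {"target_id": tid, "log10_copies": x, "cq": y}
        for tid, s in series.items()
        for x, y in s.points
    ]
    return pd.DataFrame(rows)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(payload: Mapping) -> SimulationConfig:
    kwargs = dict(payload)
    for key in ("groups", "days"):
        if key in kwargs and not isinstance(kwargs[key], tuple):
            kwargs[key] = tuple(kwargs[key])
    if "baseline_expr_range" in kwargs:
        kwargs["baseline_expr_range"] = tuple(kwargs["baseline_expr_range"])
    return SimulationConfig(**kwargs)
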