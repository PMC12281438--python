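"""Synthetic multi-modal IBD cohort generator.

Emulates the statistical structure of a longitudinal pediatric IBD biopsy
study: negative-binomial bulk RNA counts with planted persistent (elevated in
active AND healed mucosa) and transient (active only) genes, Dirichlet-
multinomial T-cell cluster compositions with a Th17-like cluster coupled to a
latent per-sample disease gradient, paired-chain TCR contigs with a
heavy-tailed clone-size distribution, and zOTU count tables with reduced
richness in disease samples.  Every planted quantity is returned in a
machine-readable truth record so downstream recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import spawn_rng

ACTIVITIES = ("active", "EH", "non-inflamed", "non-IBD")
NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    The defaults describe a desk-scale cohort: 12 IBD patients sampled at two
    sites and two timepoints (baseline active, follow-up endoscopically
    healed) plus 5 non-IBD controls, i.e. 58 biopsies.
    """

    n_patients_ibd: int = 12
    n_controls: int = 5
    locations: tuple[str, ...] = ("TI", "SC")
    timepoints_per_patient: int = 2
    n_genes: int = 2000
    n_persistent_up: int = 60
    n_transient_up: int = 60
    lfc_persistent: float = 3.0
    lfc_transient: float = 3.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (100_000, 400_000)
    n_clusters: int = 12
    dirichlet_base: tuple[float, ...] | None = None
    th17_cluster_index: int = 11
    gradient_coupling: float = 10.0
    cells_per_biopsy_range: tuple[int, int] = (300, 800)
    tcr_pairing_rate: float = 0.85
    extra_chain_rate: float = 0.05
    clone_size_tail: float = 2.5
    n_zotus: int = 300
    zotu_depth: int = 10_000
    richness_deficit: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.th17_cluster_index < self.n_clusters:
            raise ValueError("th17_cluster_index must be < n_clusters")
        if self.dirichlet_base is None:
            base = np.full(self.n_clusters, 5.0)
            # Th17-like cluster nearly absent at baseline (controls)
            base[self.th17_cluster_index] = 0.4
            self.dirichlet_base = tuple(base)
        self.validate()

    def validate(self) -> None:
        if self.n_patients_ibd < 0 or self.n_controls < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.tcr_pairing_rate <= 1:
            raise ValueError("tcr_pairing_rate must be in [0, 1]")
        if not 0 <= self.richness_deficit <= 1:
            raise ValueError("richness_deficit must be in [0, 1]")
        if self.th17_cluster_index >= self.n_clusters:
            raise ValueError("th17_cluster_index must be < n_clusters")
        if self.n_persistent_up + self.n_transient_up > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        if len(self.dirichlet_base) != self.n_clusters:
            raise ValueError("dirichlet_base length must equal n_clusters")


@dataclass
class TruthRecord:
    persistent_genes: list[str] = field(default_factory=list)
    transient_genes: list[str] = field(default_factory=list)
    coupled_genes: list[str] = field(default_factory=list)
    gradient: dict[str, float] = field(default_factory=dict)
    clone_sizes: dict[str, int] = field(default_factory=dict)
    ablated_zotus: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class StudyFixture:
    metadata: pd.DataFrame
    counts: pd.DataFrame
    cells: pd.DataFrame
    contigs: pd.DataFrame
    zotus: pd.DataFrame
    taxonomy: pd.Series
    truth: TruthRecord


def generate_metadata(config: SimConfig) -> pd.DataFrame:
    """One row per biopsy, mirroring a baseline-active -> follow-up-EH design.

    IBD patients contribute one biopsy per location at every timepoint;
    controls contribute one biopsy per location at a single endoscopy.
    """
    if config.n_patients_ibd == 0 and config.n_controls == 0:
        raise ValueError("empty design: no IBD patients and no controls")
    rng = spawn_rng(config.seed, "metadata")
    rows = []
    for i in range(config.n_patients_ibd):
        patient = f"P{i + 1:02d}"
        phenotype = "CD" if i % 2 == 0 else "UC"
        gender = "male" if i % 3 else "female"
        age_bin = ("<6", "6-12", ">12")[int(rng.integers(3))]
        anti_tnf_patient = bool(rng.random() < 0.5)
        for t in range(1, config.timepoints_per_patient + 1):
            activity = "active" if t == 1 else "EH"
            for loc in config.locations:
                rows.append(
                    dict(
                        biopsy_id=f"{patient}_T{t}_{loc}",
                        patient_id=patient,
                        patient_type="ibd",
                        phenotype=phenotype,
                        timepoint=t,
                        location=loc,
                        activity=activity,
                        batch=f"B{1 + i % 2}",
                        anti_tnf=anti_tnf_patient and t > 1,
                        gender=gender,
                        age_bin=age_bin,
                    )
                )
    for i in range(config.n_controls):
        patient = f"C{i + 1:02d}"
        gender = "male" if i % 2 else "female"
        age_bin = ("<6", "6-12", ">12")[int(rng.integers(3))]
        for loc in config.locations:
            rows.append(
                dict(
                    biopsy_id=f"{patient}_T1_{loc}",
                    patient_id=patient,
                    patient_type="control",
                    phenotype="non-IBD",
                    timepoint=1,
                    location=loc,
                    activity="non-IBD",
                    batch=f"B{1 + i % 2}",
                    anti_tnf=False,
                    gender=gender,
                    age_bin=age_bin,
                )
            )
    return pd.DataFrame(rows)


def latent_gradient(meta: pd.DataFrame, seed: int) -> pd.Series:
    """Per-biopsy latent disease gradient g in [0, 1].

    Controls sit at 0, endoscopically healed biopsies draw from U(0.2, 0.6)
    and active biopsies from U(0.6, 1.0), reproducing the qualitative
    ordering of residual disease without asserting a particular score
    distribution.  Deterministic given the seed and the biopsy order.
    """
    rng = spawn_rng(seed, "gradient")
    g = np.zeros(len(meta))
    for i, activity in enumerate(meta["activity"]):
        if activity == "active":
            g[i] = rng.uniform(0.6, 1.0)
        elif activity in ("EH", "non-inflamed"):
            g[i] = rng.uniform(0.2, 0.6)
        else:
            g[i] = 0.0
    return pd.Series(g, index=meta["biopsy_id"].to_numpy(), name="gradient")


def generate_bulk_counts(
    meta: pd.DataFrame, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, TruthRecord]:
    """Negative-binomial gene x biopsy counts with planted effects.

    Persistent genes are shifted by ``lfc_persistent`` log2 units in active
    and EH samples; transient genes only in active samples.  Half of the
    persistent genes are additionally modulated by the latent gradient so
    their expression tracks residual-disease depth within groups.

    Which genes are planted (and their baseline means) is a property of the
    configuration, keyed by ``config.seed``; the ``seed`` argument drives
    only the sampling noise, so independent batches from the same
    configuration share gene identities and differ in patients and noise.
    """
    if len(meta) == 0:
        raise ValueError("metadata is empty")
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng_genes = spawn_rng(config.seed, "genes")
    rng = spawn_rng(seed, "bulk")
    n_genes, n_samples = config.n_genes, len(meta)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    planted = rng_genes.choice(
        n_genes, size=config.n_persistent_up + config.n_transient_up, replace=False
    )
    persistent_idx = planted[: config.n_persistent_up]
    transient_idx = planted[config.n_persistent_up :]
    coupled_idx = persistent_idx[: config.n_persistent_up // 2]

    g = latent_gradient(meta, seed).to_numpy()
    is_disease = meta["activity"].isin(["active", "EH", "non-inflamed"]).to_numpy()
    is_active = (meta["activity"] == "active").to_numpy()

    baseline = rng_genes.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)
    shift = np.zeros((n_genes, n_samples))
    shift[np.ix_(persistent_idx, np.where(is_disease)[0])] = config.lfc_persistent
    # gradient modulation keeps the group-mean fold-change above the DEG
    # threshold while making expression monotone in g within groups
    shift[np.ix_(coupled_idx, np.where(is_disease)[0])] = config.lfc_persistent * (
        0.75 + 0.5 * g[is_disease]
    )
    shift[np.ix_(transient_idx, np.where(is_active)[0])] = config.lfc_transient

    lib = np.exp(
        rng.uniform(
            np.log(config.library_size_range[0]),
            np.log(config.library_size_range[1]),
            size=n_samples,
        )
    )
    size_factor = lib / np.exp(np.mean(np.log(lib)))
    mu = baseline[:, None] * np.exp2(shift) * size_factor[None, :]

    r = 1.0 / config.nb_dispersion  # NB: var = mu + dispersion * mu^2
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    frame = pd.DataFrame(counts, index=gene_ids, columns=meta["biopsy_id"].to_numpy())
    truth = TruthRecord(
        persistent_genes=[gene_ids[i] for i in persistent_idx],
        transient_genes=[gene_ids[i] for i in transient_idx],
        coupled_genes=[gene_ids[i] for i in coupled_idx],
        gradient=dict(zip(meta["biopsy_id"], g.astype(float))),
    )
    return frame, truth


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(30, 46))
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def generate_cell_table(
    meta: pd.DataFrame, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Cell-level cluster assignments plus paired-chain TCR contigs.

    Cluster composition per biopsy is Dirichlet-multinomial; the Th17-like
    cluster's concentration is inflated by ``gradient_coupling * g`` so its
    frequency rises with disease activity.  Clonotypes are drawn per patient
    from a power-law-weighted pool (clone persistence across a patient's
    biopsies), and each chain of a cell is observed with probability
    ``tcr_pairing_rate``.

    Returns ``(cells, contigs, planted_clone_sizes)``.
    """
    if len(meta) == 0:
        raise ValueError("metadata is empty")
    lo, hi = config.cells_per_biopsy_range
    if lo < 1:
        raise ValueError("cells_per_biopsy_range lower bound must be >= 1")
    rng = spawn_rng(seed, "cells")
    g = latent_gradient(meta, seed)
    base = np.asarray(config.dirichlet_base, dtype=float)

    # biopsy cell counts first, so per-patient clone structure can be planted
    n_cells_per_biopsy = {
        b: int(rng.integers(lo, hi + 1)) for b in meta["biopsy_id"]
    }
    patient_of = dict(zip(meta["biopsy_id"], meta["patient_id"]))
    patient_totals: dict[str, int] = {}
    for b, n in n_cells_per_biopsy.items():
        patient_totals[patient_of[b]] = patient_totals.get(patient_of[b], 0) + n

    # per-patient clone labels: sizes drawn from a truncated power law
    # (most clonotypes singletons, a heavy tail of expanded clones)
    clone_labels: dict[str, list[int]] = {}
    clone_seqs: dict[str, list[tuple[str, str]]] = {}
    clone_counts: dict[tuple[str, int], int] = {}
    for patient, total in patient_totals.items():
        sizes = []
        assigned = 0
        while assigned < total:
            s = min(int(rng.zipf(config.clone_size_tail)), 200, total - assigned)
            sizes.append(max(s, 1))
            assigned += max(s, 1)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        rng.shuffle(labels)
        clone_labels[patient] = list(labels)
        clone_seqs[patient] = [
            (_random_cdr3(rng), _random_cdr3(rng)) for _ in range(len(sizes))
        ]
        for idx, s in enumerate(sizes):
            clone_counts[(patient, idx)] = int(s)

    cell_rows, contig_rows = [], []
    cursor: dict[str, int] = {p: 0 for p in patient_totals}
    for _, row in meta.iterrows():
        biopsy, patient = row["biopsy_id"], row["patient_id"]
        n_cells = n_cells_per_biopsy[biopsy]
        conc = base.copy()
        conc[config.th17_cluster_index] += config.gradient_coupling * g[biopsy]
        probs = rng.dirichlet(conc)
        clusters = rng.choice(config.n_clusters, size=n_cells, p=probs)
        start = cursor[patient]
        clone_idx = clone_labels[patient][start : start + n_cells]
        cursor[patient] = start + n_cells
        for j in range(n_cells):
            cell_id = f"{biopsy}_c{j + 1:04d}"
            cell_rows.append(
                dict(
                    cell_id=cell_id,
                    biopsy_id=biopsy,
                    cluster=f"cl{clusters[j]}",
                )
            )
            cdr3a, cdr3b = clone_seqs[patient][clone_idx[j]]
            for chain, cdr3 in (("TRA", cdr3a), ("TRB", cdr3b)):
                if rng.random() < config.tcr_pairing_rate:
                    contig_rows.append(
                        dict(
                            barcode=cell_id,
                            biopsy=biopsy,
                            chain=chain,
                            cdr3_nt=cdr3,
                            umis=int(1 + rng.poisson(3)),
                            productive=True,
                        )
                    )
                    if rng.random() < config.extra_chain_rate:
                        contig_rows.append(
                            dict(
                                barcode=cell_id,
                                biopsy=biopsy,
                                chain=chain,
                                cdr3_nt=_random_cdr3(rng),
                                umis=1,
                                productive=True,
                            )
                        )
    cells = pd.DataFrame(cell_rows)
    contigs = pd.DataFrame(
        contig_rows,
        columns=["barcode", "biopsy", "chain", "cdr3_nt", "umis", "productive"],
    )
    planted_sizes = {f"{p}:{i}": n for (p, i), n in clone_counts.items()}
    return cells, contigs, planted_sizes


_TAX_VOCAB = (
    "Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides",
    "Bacteroidota;Bacteroidia;Bacteroidales;Tannerellaceae;Parabacteroides",
    "Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Blautia",
    "Bacillota;Clostridia;Oscillospirales;Ruminococcaceae;Ruminococcus",
    "Bacillota;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
    "Pseudomonadota;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia",
    "Actinomycetota;Actinomycetes;Bifidobacteriales;Bifidobacteriaceae;Bifidobacterium",
    "Verrucomicrobiota;Verrucomicrobiae;Verrucomicrobiales;Akkermansiaceae;Akkermansia",
)


def generate_zotu_table(
    meta: pd.DataFrame, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Multinomial zOTU counts with patient-specific taxa ablation in IBD.

    A ``richness_deficit`` fraction of taxa is set to zero probability in
    every sample of an IBD patient (the same set at every timepoint),
    emulating persistently reduced richness.

    Returns ``(counts, taxonomy, ablated_per_patient)``.
    """
    if len(meta) == 0:
        raise ValueError("metadata is empty")
    if not 0 <= config.richness_deficit <= 1:
        raise ValueError("richness_deficit must be in [0, 1]")
    rng = spawn_rng(seed, "zotu")
    n = config.n_zotus
    zotu_ids = [f"zOTU{i + 1:04d}" for i in range(n)]
    base = rng.dirichlet(np.full(n, 0.3))
    n_ablate = int(round(config.richness_deficit * n))
    # half the ablated set is shared across IBD patients (consistently
    # depleted taxa), the rest is patient-specific dysbiosis
    n_shared = n_ablate // 2
    shared_idx = rng.choice(n, size=n_shared, replace=False) if n_shared else np.array([], int)
    remaining = np.setdiff1d(np.arange(n), shared_idx)

    ablated: dict[str, list[str]] = {}
    for patient, ptype in meta.groupby("patient_id")["patient_type"].first().items():
        if ptype == "ibd" and n_ablate > 0:
            extra = rng.choice(remaining, size=n_ablate - n_shared, replace=False)
            idx = np.concatenate([shared_idx, extra])
            ablated[patient] = sorted(zotu_ids[i] for i in idx)
        else:
            ablated[patient] = []

    cols = {}
    for _, row in meta.iterrows():
        probs = base * np.exp(rng.normal(0.0, 0.5, size=n))  # sample-level jitter
        gone = ablated[row["patient_id"]]
        if gone:
            probs[[int(z[4:]) - 1 for z in gone]] = 0.0
        probs = probs / probs.sum()
        cols[row["biopsy_id"]] = rng.multinomial(config.zotu_depth, probs)
    counts = pd.DataFrame(cols, index=zotu_ids)
    taxonomy = pd.Series(
        [
            _TAX_VOCAB[i % len(_TAX_VOCAB)] + f";zOTU{i + 1:04d}"
            for i in range(n)
        ],
        index=zotu_ids,
        name="taxonomy",
    )
    return counts, taxonomy, ablated


def generate_fixture(config: SimConfig) -> StudyFixture:
    """Generate the full multi-modal cohort from one configuration."""
    meta = generate_metadata(config)
    counts, truth = generate_bulk_counts(meta, config, config.seed)
    cells, contigs, clone_sizes = generate_cell_table(meta, config, config.seed)
    zotus, taxonomy, ablated = generate_zotu_table(meta, config, config.seed)
    truth.clone_sizes = clone_sizes
    truth.ablated_zotus = ablated
    return StudyFixture(
        metadata=meta,
        counts=counts,
        cells=cells,
        contigs=contigs,
        zotus=zotus,
        taxonomy=taxonomy,
        truth=truth,
    )


def write_fixture(fixture: StudyFixture, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    fixture.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    fixture.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    fixture.contigs.to_csv(outdir / "contigs.csv", index=False)
    zot = fixture.zotus.copy()
    zot["taxonomy"] = fixture.taxonomy
    zot.to_csv(outdir / "zotus.tsv", sep="\t", index_label="zotu_id")
    (outdir / "truth.json").write_text(fixture.truth.to_json())
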