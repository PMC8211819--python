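"""Synthetic data with known ground truth for every analysis stage.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* a genome of uniform-composition chromosomes with *planted* RLFS-prone
  cassettes (a G-tract seed, short linker, and a 300-nt 45%-G extension)
  at Poisson-placed, strand-labelled positions;
* non-overlapping stranded gene models with exon counts, where "responder"
  genes preferentially sit on same-strand planted cassettes (odds
  multiplied by ``rlfs_enrichment_effect``);
* negative-binomial count matrices over four groups (control/knockdown x
  normoxia/hypoxia) in which responders shift by ``de_log2fc`` only in the
  knockdown-hypoxia group;
* cohort expression tables where one query gene and a 6-gene panel are
  coupled through a Gaussian copula hitting a target Spearman correlation
  (``rho_S = (6/pi) asin(r/2)``, hence ``r = 2 sin(pi rho_S / 6)``);
* fibre-track, Ct and foci tables with planted effect sizes.

Everything is driven by one :class:`SimulationConfig` and one seed;
identical config + seed reproduces byte-identical outputs. Truth tables
record planted loci, responder identities/directions and planted assay
effects, sufficient to score each downstream stage.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io

GROUPS = ("siCTRL_norm", "siSETX_norm", "siCTRL_hyp", "siSETX_hyp")
KD_HYPOXIA_GROUP = "siSETX_hyp"
P53_PANEL_GENES = ("BTG2", "CYFIP2", "INPP5D", "KANK3", "PHLDA3", "SULF2")
QUERY_GENE = "SETX"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_G = np.frombuffer(b"ACT", dtype=np.uint8)
_RC_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _RC_TABLE[a] = b


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Counts must all be >= 1 and ``cohort_rho`` within [-1, 1]; validation
    happens at construction.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 250_000
    planted_rlfs_rate: float = 20.0  # expected planted loci per 100 kb
    n_genes: int = 400
    mean_gene_length_bp: float = 800.0
    rlfs_enrichment_effect: float = 10.0
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.05
    de_log2fc: float = 2.0
    cohort_n: int = 400
    cohort_rho: float = 0.6
    # --- structure knobs beyond the core study conditions ---
    responder_fraction: float = 0.15
    noncoding_fraction: float = 0.05
    min_gene_length_bp: int = 200
    min_gene_gap_bp: int = 20
    base_expression_log_mean: float = math.log(150.0)
    base_expression_log_sd: float = 1.0
    cohort_n_background_genes: int = 20
    cohort_panel_noise_sd: float = 0.0
    ct_fold_change: float = 2.0
    ct_noise_sd: float = 0.15
    ct_replicates: int = 3
    foci_positive_fraction: float = 0.4
    foci_cells_per_condition: int = 200
    fibre_tracks_per_condition: int = 150
    fibre_mean_px: dict = field(default_factory=lambda: {"normoxia": 120.0, "hypoxia": 90.0})
    cassette_extension_len: int = 300
    cassette_extension_g_fraction: float = 0.45
    cassette_max_linker: int = 40

    def __post_init__(self):
        for name in ("n_chromosomes", "chrom_length_bp", "n_genes",
                     "n_samples_per_group", "cohort_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (-1.0 <= self.cohort_rho <= 1.0):
            raise ValueError("cohort_rho must be within [-1, 1]")
        if self.planted_rlfs_rate < 0:
            raise ValueError("planted_rlfs_rate must be >= 0")
        if self.rlfs_enrichment_effect < 1:
            raise ValueError("rlfs_enrichment_effect must be >= 1")
        if self.nb_dispersion < 0 or self.mean_gene_length_bp <= 0:
            raise ValueError("nb_dispersion must be >= 0 and gene length > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(d) - known:
            raise ValueError(f"unknown SimulationConfig fields: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthTables:
    planted_rlfs: pd.DataFrame  # chrom, start, end, strand
    responder_genes: dict[str, int]  # gene_id -> +1 (up) / -1 (down)
    cohort_true_rho: float
    ct_fold_change: float = 1.0
    foci_positive_fraction: float = 0.0


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("genome", "annotation", "expression", "cohort", "assays")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _RC_TABLE[arr][::-1]


def _make_cassette(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """RIZ-like seed (G3 N1-5 G3 N1-5 G3) + linker + G-rich extension."""
    parts = [b"GGG"]
    for _ in range(2):
        n = rng.integers(1, 6)
        parts.append(rng.choice(_NON_G, n).tobytes())
        parts.append(b"GGG")
    linker_len = int(rng.integers(0, config.cassette_max_linker + 1))
    parts.append(rng.choice(_NON_G, linker_len).tobytes())
    ext_len = config.cassette_extension_len
    gmask = rng.random(ext_len) < config.cassette_extension_g_fraction
    ext = rng.choice(_NON_G, ext_len)
    ext[gmask] = ord("G")
    parts.append(ext.tobytes())
    return np.frombuffer(b"".join(parts), dtype=np.uint8).copy()


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], TruthTables]:
    """Background-uniform chromosomes with planted RLFS cassettes.

    The number of cassettes per chromosome is a Poisson draw at
    ``planted_rlfs_rate`` per 100 kb; placements avoid overlap by
    rejection. Raises if a chromosome is too short to host a cassette.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["genome"]
    sequences: dict[str, str] = {}
    planted = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        length = config.chrom_length_bp
        seq = rng.choice(_BASES, length)
        n_loci = int(rng.poisson(config.planted_rlfs_rate * length / 1e5))
        occupied: list[tuple[int, int]] = []
        for _ in range(n_loci):
            cassette = _make_cassette(rng, config)
            clen = cassette.size
            if length < clen:
                raise ValueError(
                    f"{chrom} ({length} bp) too short to host a planted locus ({clen} bp)"
                )
            placed = False
            for _attempt in range(1000):
                start = int(rng.integers(0, length - clen + 1))
                end = start + clen
                if all(end + 10 <= s or e + 10 <= start for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise ValueError(f"could not place {n_loci} non-overlapping loci on {chrom}")
            strand = "+" if rng.random() < 0.5 else "-"
            seq[start:end] = cassette if strand == "+" else _revcomp_arr(cassette)
            occupied.append((start, end))
            planted.append({"chrom": chrom, "start": start, "end": end, "strand": strand})
        sequences[chrom] = seq.tobytes().decode()
    planted_df = (
        pd.DataFrame(planted, columns=["chrom", "start", "end", "strand"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    truth = TruthTables(planted_rlfs=planted_df, responder_genes={}, cohort_true_rho=config.cohort_rho,
                        ct_fold_change=config.ct_fold_change,
                        foci_positive_fraction=config.foci_positive_fraction)
    return sequences, truth


def simulate_annotation(config: SimulationConfig, sequences: dict[str, str],
                        truth: TruthTables,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Non-overlapping stranded gene models; fills ``truth.responder_genes``.

    Genes are laid out by apportioning the free space between them
    (exponential gaps normalised to fit), so dense configurations place
    deterministically; an explicit error names the constraint when the
    genes cannot fit. Responders are then drawn with odds multiplied by
    ``rlfs_enrichment_effect`` for genes whose 2 kb-flanked window
    overlaps a same-strand planted cassette.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["annotation"]
    chroms = list(sequences)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    rows = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        length = len(sequences[chrom])
        lens = np.maximum(
            config.min_gene_length_bp,
            rng.gamma(2.0, config.mean_gene_length_bp / 2.0, n).astype(int),
        )
        occupied = int(lens.sum()) + (n + 1) * config.min_gene_gap_bp
        if occupied > length:
            raise ValueError(
                f"cannot place {n} non-overlapping genes on {chrom}: "
                f"{occupied} bp needed (gene lengths + minimum gaps) but only {length} bp available"
            )
        free = length - int(lens.sum()) - (n + 1) * config.min_gene_gap_bp
        gaps = rng.exponential(1.0, n + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(int)
        pos = config.min_gene_gap_bp + gaps[0]
        for i in range(n):
            start, end = pos, pos + int(lens[i])
            rows.append(
                {
                    "gene_id": f"gene{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "exon_count": 1 + int(rng.poisson(4)),
                    "biotype": "protein_coding"
                    if rng.random() >= config.noncoding_fraction
                    else "lncRNA",
                }
            )
            gid += 1
            pos = end + config.min_gene_gap_bp + gaps[i + 1]
    genes = pd.DataFrame(rows)

    coding = genes[genes["biotype"] == "protein_coding"]
    planted = truth.planted_rlfs
    weights = np.ones(len(coding))
    for i, (_, g) in enumerate(coding.iterrows()):
        sel = (
            (planted["chrom"] == g["chrom"])
            & (planted["strand"] == g["strand"])
            & (planted["start"] < g["end"] + 2000)
            & (planted["end"] > g["start"] - 2000)
        )
        if sel.any():
            weights[i] = config.rlfs_enrichment_effect
    k = min(len(coding), max(2, round(config.responder_fraction * config.n_genes)))
    chosen = rng.choice(len(coding), size=k, replace=False, p=weights / weights.sum())
    directions = rng.choice([1, -1], size=k)
    truth.responder_genes = {
        coding.iloc[int(i)]["gene_id"]: int(d) for i, d in zip(chosen, directions)
    }
    return genes


def simulate_expression(genes: pd.DataFrame, truth: TruthTables,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix and design table.

    Four groups (control/knockdown x normoxia/hypoxia) with
    ``n_samples_per_group`` replicates each; size factors are fixed at 1.
    Responder genes shift by ``de_log2fc`` (in their truth direction) only
    in the knockdown-hypoxia group.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["expression"]
    gene_ids = list(genes["gene_id"])
    samples, groups = [], []
    for group in GROUPS:
        for r in range(1, config.n_samples_per_group + 1):
            samples.append(f"{group}_r{r}")
            groups.append(group)
    design = pd.DataFrame({"sample": samples, "group": groups})
    base = rng.lognormal(config.base_expression_log_mean,
                         config.base_expression_log_sd, len(gene_ids))
    mu = np.tile(base[:, None], (1, len(samples)))
    kd_cols = [i for i, g in enumerate(groups) if g == KD_HYPOXIA_GROUP]
    for gi, gid in enumerate(gene_ids):
        d = truth.responder_genes.get(gid)
        if d:
            mu[gi, kd_cols] *= 2.0 ** (d * config.de_log2fc)
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    return pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples), design


def simulate_cohort(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Cohort expression table (genes x samples) with a tunable Spearman
    correlation between the query gene and the panel median.

    A bivariate Gaussian copula couples the query gene's latent score to a
    single latent panel score at Pearson ``r = 2 sin(pi rho_S / 6)``; each
    panel gene is a lognormal (monotone) transform of the panel score, so
    the induced rank correlation hits ``cohort_rho`` (exactly at |rho|=1).
    ``cohort_panel_noise_sd`` adds per-gene latent noise at the cost of a
    slight attenuation.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["cohort"]
    n = config.cohort_n
    r = 2.0 * math.sin(math.pi * config.cohort_rho / 6.0)
    z_query = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z_panel = r * z_query + math.sqrt(max(0.0, 1.0 - r * r)) * e
    rows = {QUERY_GENE: np.exp(2.5 + 0.8 * z_query)}
    for j, gene in enumerate(P53_PANEL_GENES):
        noise = (
            config.cohort_panel_noise_sd * rng.standard_normal(n)
            if config.cohort_panel_noise_sd > 0
            else 0.0
        )
        sigma = 0.4 + 0.1 * j
        rows[gene] = np.exp(1.0 + 0.3 * j + sigma * (z_panel + noise))
    for b in range(config.cohort_n_background_genes):
        rows[f"BG{b:03d}"] = np.exp(2.0 + 0.7 * rng.standard_normal(n))
    samples = [f"sample{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(rows, index=samples).T.rename_axis("gene_id")


def simulate_assay_tables(config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fibre-track, Ct and foci tables with planted truth.

    * Fibre lengths: gamma-distributed pixels around per-condition means.
    * Ct: target/reference Ct values whose mean ddCt equals
      ``-log2(ct_fold_change)`` for the treated condition; Gaussian noise
      at ``ct_noise_sd`` (0 gives exact recovery).
    * Foci: cells are positive (count > 5) with probability
      ``foci_positive_fraction`` in the treated condition; negative cells
      have counts <= 5 by construction.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["assays"]
    fib_rows = []
    for condition, mean_px in config.fibre_mean_px.items():
        x = rng.gamma(4.0, mean_px / 4.0, config.fibre_tracks_per_condition)
        for i, xi in enumerate(x):
            fib_rows.append(
                {"track_id": f"{condition}_{i:03d}", "condition": condition,
                 "x_pixels": float(xi)}
            )
    fibre = pd.DataFrame(fib_rows)

    ct_rows = []
    base_target, base_ref = 24.0, 12.0
    for condition in ("control", "treated"):
        shift = -math.log2(config.ct_fold_change) if condition == "treated" else 0.0
        for r in range(1, config.ct_replicates + 1):
            ct_rows.append(
                {
                    "sample": f"{condition}_r{r}",
                    "target": QUERY_GENE,
                    "ct_target": base_target + shift + config.ct_noise_sd * rng.standard_normal(),
                    "ct_ref": base_ref + config.ct_noise_sd * rng.standard_normal(),
                    "condition": condition,
                }
            )
    ct = pd.DataFrame(ct_rows)

    foci_rows = []
    fractions = {"control": 0.1, "treated": config.foci_positive_fraction}
    for condition, frac in fractions.items():
        positive = rng.random(config.foci_cells_per_condition) < frac
        counts = np.where(
            positive,
            6 + rng.poisson(5, config.foci_cells_per_condition),
            np.minimum(5, rng.poisson(1.5, config.foci_cells_per_condition)),
        )
        for i, c in enumerate(counts):
            foci_rows.append(
                {"cell_id": f"{condition}_{i:03d}", "marker": "53BP1",
                 "condition": condition, "foci_count": int(c)}
            )
    foci = pd.DataFrame(foci_rows)
    return fibre, ct, foci


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator stage with per-stage RNG streams derived from
    ``config.seed``; returns a dict of in-memory artefacts + truth."""
    rngs = _stage_rngs(config.seed)
    sequences, truth = simulate_genome(config, rngs["genome"])
    genes = simulate_annotation(config, sequences, truth, rngs["annotation"])
    counts, design = simulate_expression(genes, truth, config, rngs["expression"])
    cohort = simulate_cohort(config, rngs["cohort"])
    fibre, ct, foci = simulate_assay_tables(config, rngs["assays"])
    return {
        "sequences": sequences,
        "truth": truth,
        "genes": genes,
        "counts": counts,
        "design": design,
        "cohort": cohort,
        "fibre": fibre,
        "ct": ct,
        "foci": foci,
    }


def write_simulation(config: SimulationConfig, outdir) -> dict:
    """Write all artefacts to ``outdir`` and return a manifest with the
    seed and per-file checksums."""
    out = io.ensure_dir(outdir)
    art = simulate_all(config)
    io.write_fasta(art["sequences"], out / "genome.fa")
    io.write_bed6(
        art["truth"].planted_rlfs.assign(
            name=lambda d: [f"planted{i:04d}" for i in range(len(d))], score=0
        ),
        out / "planted.bed",
    )
    io.write_table(art["genes"], out / "genes.tsv")
    io.write_bed6(io.genes_to_bed6(art["genes"]), out / "genes.bed")
    io.write_table(art["counts"].reset_index(), out / "counts.tsv")
    io.write_table(art["design"], out / "design.tsv")
    io.write_table(art["cohort"].reset_index(), out / "cohort.tsv")
    io.write_table(art["fibre"], out / "fibre.tsv")
    io.write_table(art["ct"], out / "ct.tsv")
    io.write_table(art["foci"], out / "foci.tsv")
    truth_json = {
        "responder_genes": art["truth"].responder_genes,
        "cohort_true_rho": art["truth"].cohort_true_rho,
        "ct_fold_change": art["truth"].ct_fold_change,
        "foci_positive_fraction": art["truth"].foci_positive_fraction,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    files = sorted(
        p.name
        for p in out.iterdir()
        if p.suffix in {".fa", ".bed", ".tsv", ".json", ".yaml"} and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "checksums": {f: io.sha256_file(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
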