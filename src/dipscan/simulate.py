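"""Synthetic two-gate sort-seq generator for domain-insertion screens.

Emulates the statistical structure of a surface-expression FACS-seq
experiment: a motif x position insertion library with an internal
flexible-linker control, a planted ground-truth fitness surface with
contiguous positional classes and motif groups, logistic gating of cells
into label-high/label-low gates, multinomial cell and read sampling per
sequencing subpool, per-replicate variant dropout, and paired junction
reads for the insertion caller.

Defaults are the desk-scale study conditions used throughout the test
suite: 50 recipient positions x 40 motifs (including the control), two
replicates, 1e5 reads per gate and replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "LibraryDesign", "TruthSurface", "SortModel", "EffectParams",
    "make_design", "simulate_true_fitness", "simulate_sort_counts",
    "simulate_reads", "simulate_property_tables", "write_fastq",
    "CONTROL_MOTIF_ID", "CONTROL_MOTIF_AA",
]

CONTROL_MOTIF_ID = "flex_linker"
CONTROL_MOTIF_AA = "AGSAGSA"
# one codon per residue of the AGSAGSA flexible linker
CONTROL_MOTIF_NT = "GCTGGTAGCGCTGGTAGCGCT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

POSITION_CLASSES = ("rigid", "intermediate", "flexible")
MOTIF_GROUPS = ("structured", "unstructured", "hydrophobic")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryDesign:
    """An insertion library: recipient CDS, motifs, positions, subpools."""
    recipient_length: int
    recipient_cds: str
    motif_ids: tuple[str, ...]
    motif_nt: dict[str, str]
    positions: tuple[int, ...]
    subpool_map: dict[tuple[int, str], str]
    control_motif_id: str = CONTROL_MOTIF_ID
    context5: str = ""
    context3: str = ""

    @property
    def variants(self) -> list[tuple[int, str]]:
        return [(p, m) for m in self.motif_ids for p in self.positions]

    @property
    def n_variants(self) -> int:
        return len(self.motif_ids) * len(self.positions)

    def variant_sequence(self, position: int, motif_id: str) -> str:
        """Nucleotide sequence of the CDS with the motif inserted after
        residue ``position`` (1-based)."""
        j = 3 * position
        return (self.recipient_cds[:j] + self.motif_nt[motif_id]
                + self.recipient_cds[j:])


@dataclass
class TruthSurface:
    """Planted ground truth behind a synthetic screen."""
    position_class: dict[int, str]
    motif_group: dict[str, str]
    fitness_true: pd.DataFrame  # positions x motifs
    params: "EffectParams"


@dataclass(frozen=True)
class EffectParams:
    """Main/interaction effects of positional classes and motif groups.

    Defaults plant a rigid/structured incompatibility and a
    flexible/structured bonus (structured motifs favored at flexible
    termini), with modest per-variant Gaussian noise.
    """
    class_effects: dict = field(default_factory=lambda: {
        "rigid": -2.0, "intermediate": 0.0, "flexible": 1.5})
    group_effects: dict = field(default_factory=lambda: {
        "structured": -1.0, "unstructured": 1.0, "hydrophobic": -0.5})
    interaction: dict = field(default_factory=lambda: {
        ("rigid", "structured"): -2.0, ("flexible", "structured"): 1.5,
        ("rigid", "hydrophobic"): 1.0, ("flexible", "hydrophobic"): -1.0})
    noise_sd: float = 0.5


@dataclass(frozen=True)
class SortModel:
    """Two-gate sorting and sequencing model.

    P(high gate) = logistic(gate_logit_slope * fitness + intercept); cells
    and reads are allocated by multinomial sampling within each subpool and
    gate; ``dropout_rate`` of non-control variants are zeroed per replicate.
    """
    gate_logit_slope: float = 1.0
    gate_logit_intercept: float = 0.0
    cells_per_gate: int = 40_000
    reads_per_gate: int = 100_000
    replicates: int = 2
    dropout_rate: float = 0.05

    def __post_init__(self):
        if self.gate_logit_slope < 0 or self.cells_per_gate <= 0 \
                or self.reads_per_gate < 0 or self.replicates < 1:
            raise ValueError("sort model sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def _random_cds(rng: np.random.Generator, n_nt: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n_nt))


def make_design(recipient_length: int = 50, n_motifs: int = 39,
                subpool_size: int | None = None, seed: int = 0,
                motif_aa_length_range: tuple[int, int] = (5, 15),
                context_nt: int = 60) -> LibraryDesign:
    """Build a library: every motif (plus the control) at every position.

    ``n_motifs`` counts non-control motifs, so the library holds
    ``(n_motifs + 1) * recipient_length`` variants. Subpools partition the
    variant list into consecutive chunks of ``subpool_size``; ``None``
    yields a single subpool.
    """
    if recipient_length < 2:
        raise ValueError("recipient_length must be >= 2")
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    if subpool_size is not None and subpool_size < 1:
        raise ValueError("subpool_size must be positive")
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, 3 * recipient_length)
    ctx5 = _random_cds(rng, context_nt)
    ctx3 = _random_cds(rng, context_nt)
    lo, hi = motif_aa_length_range
    motif_ids = [CONTROL_MOTIF_ID] + [f"motif_{k:03d}" for k in range(n_motifs)]
    motif_nt = {CONTROL_MOTIF_ID: CONTROL_MOTIF_NT}
    for mid in motif_ids[1:]:
        motif_nt[mid] = _random_cds(rng, 3 * int(rng.integers(lo, hi + 1)))
    positions = tuple(range(1, recipient_length + 1))
    variants = [(p, m) for m in motif_ids for p in positions]
    if subpool_size is None:
        subpool_map = {v: "sp0" for v in variants}
    else:
        subpool_map = {v: f"sp{i // subpool_size}"
                       for i, v in enumerate(variants)}
    return LibraryDesign(
        recipient_length=recipient_length, recipient_cds=cds,
        motif_ids=tuple(motif_ids), motif_nt=motif_nt, positions=positions,
        subpool_map=subpool_map, context5=ctx5, context3=ctx3)


def _contiguous_blocks(rng: np.random.Generator, length: int,
                       fractions: dict[str, float]) -> dict[int, str]:
    labels = list(fractions)
    sizes = np.floor(np.array([fractions[c] for c in labels]) * length)
    sizes = sizes.astype(int)
    # distribute the remainder deterministically from the rng
    while sizes.sum() < length:
        sizes[rng.integers(0, len(sizes))] += 1
    order = rng.permutation(len(labels))
    assignment, pos = {}, 1
    for idx in order:
        for _ in range(sizes[idx]):
            assignment[pos] = labels[idx]
            pos += 1
    return assignment


def simulate_true_fitness(design: LibraryDesign,
                          class_fractions: dict[str, float] | None = None,
                          group_fractions: dict[str, float] | None = None,
                          effect_params: EffectParams | None = None,
                          seed: int = 0) -> TruthSurface:
    """Plant a block-structured true fitness surface.

    Positions receive contiguous class blocks (mimicking contiguous
    structural regions); motifs get group labels; fitness is additive in
    the class and group main effects plus their interaction, with Gaussian
    noise. The control motif's fitness is 0 by definition (it is the
    normalization anchor).
    """
    class_fractions = class_fractions or {
        "rigid": 0.4, "intermediate": 0.3, "flexible": 0.3}
    group_fractions = group_fractions or {
        "structured": 0.35, "unstructured": 0.4, "hydrophobic": 0.25}
    for name, fr in (("class_fractions", class_fractions),
                     ("group_fractions", group_fractions)):
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")
    params = effect_params or EffectParams()
    rng = np.random.default_rng(seed)
    position_class = _contiguous_blocks(rng, design.recipient_length,
                                        class_fractions)
    others = [m for m in design.motif_ids if m != design.control_motif_id]
    groups = list(group_fractions)
    probs = np.array([group_fractions[g] for g in groups])
    motif_group = {m: groups[i] for m, i in
                   zip(others, rng.choice(len(groups), size=len(others),
                                          p=probs))}
    motif_group[design.control_motif_id] = "control"

    fitness = pd.DataFrame(0.0, index=list(design.positions),
                           columns=list(design.motif_ids))
    for m in others:
        g = motif_group[m]
        for p in design.positions:
            c = position_class[p]
            mu = (params.class_effects.get(c, 0.0)
                  + params.group_effects.get(g, 0.0)
                  + params.interaction.get((c, g), 0.0))
            fitness.loc[p, m] = mu
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd,
                           size=(len(design.positions), len(others)))
        fitness.loc[:, others] += noise
    fitness[design.control_motif_id] = 0.0
    return TruthSurface(position_class=position_class,
                        motif_group=motif_group, fitness_true=fitness,
                        params=params)


def _split_total(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder split of an integer total proportional to weights."""
    weights = np.asarray(weights, dtype=float)
    frac = weights / weights.sum() * total
    base = np.floor(frac).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(frac - base))
        base[order[:rem]] += 1
    return base


def simulate_sort_counts(design: LibraryDesign, truth: TruthSurface,
                         sort_model: SortModel | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Sample the gated count table for a synthetic screen.

    Returns a long-form table with columns position, motif_id, gate
    ('high'/'low'), replicate, subpool, batch, count. Each replicate is
    its own collection batch. Dropout zeroes the counts of a random
    non-control variant subset after sampling, so total reads after
    dropout are <= the configured depth.
    """
    sm = sort_model or SortModel()
    rng = np.random.default_rng(seed)
    variants = design.variants
    n = len(variants)
    fit = np.array([truth.fitness_true.loc[p, m] for p, m in variants])
    p_high = expit(sm.gate_logit_slope * fit + sm.gate_logit_intercept)
    subpools = np.array([design.subpool_map[v] for v in variants])
    pool_ids = sorted(set(subpools))
    pool_sizes = np.array([(subpools == sp).sum() for sp in pool_ids])
    is_control = np.array([m == design.control_motif_id for _, m in variants])

    # one library, sorted in every replicate: abundance is drawn once
    abundance = rng.lognormal(0.0, 0.3, size=n)
    records = []
    for rep in range(1, sm.replicates + 1):
        dropped = np.zeros(n, dtype=bool)
        if sm.dropout_rate > 0:
            candidates = np.flatnonzero(~is_control)
            k = int(round(sm.dropout_rate * candidates.size))
            if k:
                dropped[rng.choice(candidates, size=k, replace=False)] = True
        cells_split = _split_total(sm.cells_per_gate, pool_sizes)
        reads_split = _split_total(sm.reads_per_gate, pool_sizes)
        for sp, n_cells, n_reads in zip(pool_ids, cells_split, reads_split):
            mask = subpools == sp
            idx = np.flatnonzero(mask)
            for gate, pg in (("high", p_high), ("low", 1.0 - p_high)):
                w = abundance[idx] * pg[idx]
                if w.sum() <= 0 or n_reads == 0:
                    counts = np.zeros(idx.size, dtype=int)
                else:
                    cells = rng.multinomial(n_cells, w / w.sum())
                    if cells.sum() == 0:
                        counts = np.zeros(idx.size, dtype=int)
                    else:
                        counts = rng.multinomial(n_reads,
                                                 cells / cells.sum())
                counts[dropped[idx]] = 0
                for v_i, c in zip(idx, counts):
                    pos, motif = variants[v_i]
                    records.append((pos, motif, gate, rep, sp,
                                    f"batch{rep}", int(c)))
    return pd.DataFrame(records, columns=["position", "motif_id", "gate",
                                          "replicate", "subpool", "batch",
                                          "count"])


def simulate_reads(design: LibraryDesign, counts: pd.DataFrame,
                   read_length: int = 100, error_rate: float = 0.0,
                   seed: int = 0, flank: int = 20):
    """Emit paired junction reads for every counted variant.

    Each count unit yields one read pair: the forward mate spans the
    upstream recipient/motif junction and the reverse mate (reverse
    complemented) spans the motif/downstream-recipient junction, each with
    at least ``flank`` matching nucleotides on both sides. Read names
    encode the ground truth (motif, position, gate, replicate, subpool,
    batch) for test assertions. Returns a list of
    ``(name, read1, read2)`` tuples.
    """
    if read_length < 2 * flank or read_length < 30:
        raise ValueError("read_length must be >= 2 * flank and >= 30 nt")
    # independent streams so fragment placement is invariant to error_rate
    rng, rng_err = (np.random.default_rng(s)
                    for s in np.random.SeedSequence(seed).spawn(2))
    genome5 = design.context5
    frag_len = int(1.6 * read_length)
    pairs = []
    serial = 0
    for row in counts.itertuples(index=False):
        if row.count <= 0:
            continue
        motif_nt = design.motif_nt[row.motif_id]
        v = genome5 + design.variant_sequence(row.position, row.motif_id) \
            + design.context3
        j1 = len(genome5) + 3 * row.position          # first inserted nt
        j2 = j1 + len(motif_nt)                       # recipient resumes
        # fragment start range: forward mate spans j1, reverse mate spans j2
        lo = max(0, j1 + flank - read_length, j2 + flank - frag_len)
        hi = min(j1 - flank, j2 + read_length - flank - frag_len,
                 len(v) - frag_len)
        if hi < lo:
            lo = hi = max(0, min(j1 - flank, len(v) - frag_len))
        for _ in range(int(row.count)):
            s = int(rng.integers(lo, hi + 1))
            frag = v[s:s + frag_len]
            r1 = frag[:read_length]
            r2 = reverse_complement(frag[-read_length:])
            if error_rate > 0:
                r1 = _mutate(rng_err, r1, error_rate)
                r2 = _mutate(rng_err, r2, error_rate)
            name = (f"{row.motif_id}|pos{row.position}|{row.gate}"
                    f"|rep{row.replicate}|{row.subpool}|{row.batch}"
                    f"|{serial}")
            pairs.append((name, r1, r2))
            serial += 1
    return pairs


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def write_fastq(pairs, path_r1, path_r2):
    """Write simulated read pairs as a FASTQ pair (constant quality)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord

    def records(mate):
        for name, r1, r2 in pairs:
            seq = r1 if mate == 1 else r2
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    with open(path_r1, "w") as fh:
        seq_write(records(1), fh, "fastq")
    with open(path_r2, "w") as fh:
        seq_write(records(2), fh, "fastq")


def simulate_property_tables(design: LibraryDesign, truth: TruthSurface,
                             coupling: dict | None = None, seed: int = 0,
                             n_recipient_nuisance: int = 4,
                             n_motif_nuisance: int = 4,
                             duplicate_feature: str | None = None):
    """Draw correlated recipient/motif property tables.

    ``coupling`` maps feature names to specs:
    ``{"axis": "position"|"motif", "means": {label: mean}, "sd": float}``;
    informative features are drawn with class/group-dependent means,
    nuisance features are independent standard normals.
    ``duplicate_feature`` adds an exact copy of a feature (correlation 1)
    to exercise redundancy reduction. Returns ``(recipient_df, motif_df)``.
    """
    rng = np.random.default_rng(seed)
    coupling = coupling or {}
    positions = list(design.positions)
    motifs = [m for m in design.motif_ids]
    rec = pd.DataFrame(index=positions)
    rec.index.name = "position"
    mot = pd.DataFrame(index=motifs)
    mot.index.name = "motif_id"
    for name, spec in coupling.items():
        means, sd = spec["means"], spec.get("sd", 0.5)
        if spec["axis"] == "position":
            mu = np.array([means.get(truth.position_class[p], 0.0)
                           for p in positions])
            rec[name] = mu + rng.normal(0, sd, len(positions))
        else:
            mu = np.array([means.get(truth.motif_group[m], 0.0)
                           for m in motifs])
            mot[name] = mu + rng.normal(0, sd, len(motifs))
    for k in range(n_recipient_nuisance):
        rec[f"rec_noise_{k}"] = rng.normal(0, 1, len(positions))
    for k in range(n_motif_nuisance):
        mot[f"motif_noise_{k}"] = rng.normal(0, 1, len(motifs))
    if duplicate_feature is not None:
        for df in (rec, mot):
            if duplicate_feature in df.columns:
                df[f"{duplicate_feature}_copy"] = df[duplicate_feature]
    return rec, mot
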