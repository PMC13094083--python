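"""Generative simulator of dual-gRNA editing outcomes and their measurement.

The model follows the biology of a dual-cut experiment in protoplasts: a
fraction of cells receives the construct; in transfected cells each allele is
cut at each site with a per-site probability; alleles cut at both sites
resolve as an inversion, a large inter-cut deletion, perfect re-ligation, or
re-ligation with small indel scars at one or both junctions; alleles cut at a
single site repair perfectly or with a scar. Inversions and deletions can
therefore only arise when both sites cut — the zero-inflation structure the
downstream estimators rely on.

Three measurement processes are emulated: Poisson partitioning of genome
copies into fixed-volume cdPCR droplets with two-channel fluorescence,
short amplicon reads around each cut site, and full-interval long amplicon
reads carrying complete junction structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cdpcr import genome_copies
from .locus import DNA_ALPHABET, LocusPair, revcomp

ALLELE_CLASSES = (
    "wild_type",
    "indel_fixed_only",
    "indel_var_only",
    "indel_both",
    "inversion",
    "deletion",
)

EDITED_COLUMNS = (
    "label",
    "indel_fixed",
    "indel_fixed_seq",
    "indel_var",
    "indel_var_seq",
    "ins_left_seq",
    "ins_right_seq",
)


class LongReadUnsupportedError(ValueError):
    """Raised when the inter-cut interval exceeds the long-amplicon ceiling."""


# ---------------------------------------------------------------------------
# distributions


def _validate_dist(dist: dict[int, float], name: str) -> None:
    if not dist:
        raise ValueError(f"{name} must be non-empty")
    probs = np.array(list(dist.values()), dtype=float)
    if (probs < 0).any():
        raise ValueError(f"{name} has negative probabilities")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must sum to 1 (got {probs.sum():.6g})")


def default_indel_size_dist() -> dict[int, float]:
    """Signed indel sizes at a resolved cut site.

    Point masses at -3/-6/-9 bp deletions (the microhomology-mediated scars
    dominating imperfect repair at these sites) plus a geometric tail of
    insertions from +1 bp, truncated at +80 bp.
    """
    dist = {-3: 0.35, -6: 0.25, -9: 0.15}
    tail_mass = 0.25
    p = 0.5
    ks = np.arange(1, 81)
    w = (1 - p) ** (ks - 1) * p
    w = w / w.sum() * tail_mass
    dist.update({int(k): float(x) for k, x in zip(ks, w)})
    return dist


def default_junction_insert_dist() -> dict[int, float]:
    """Insertion lengths at rearrangement junctions: mostly 0, geometric tail.

    Truncated at 80 bp by default; longer templated insertions (such as the
    ~193 bp class seen at some repair sites) can be enabled by supplying a
    distribution with support up to 200 bp.
    """
    dist = {0: 0.8}
    tail_mass = 0.2
    p = 0.15
    ks = np.arange(1, 81)
    w = (1 - p) ** (ks - 1) * p
    w = w / w.sum() * tail_mass
    dist.update({int(k): float(x) for k, x in zip(ks, w)})
    return dist


def _draw(dist: dict[int, float], rng: np.random.Generator, size: int) -> np.ndarray:
    keys = np.fromiter(dist.keys(), dtype=np.int64)
    probs = np.fromiter(dist.values(), dtype=float)
    probs = probs / probs.sum()
    if size == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(keys, size=size, p=probs)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


# ---------------------------------------------------------------------------
# generative model


@dataclass(frozen=True)
class OutcomeModel:
    """Per-sample generative parameters of the editing experiment.

    p_transfect : fraction of cells receiving the construct.
    p_cut_fixed, p_cut_var : per-allele cleavage probability at each site,
        conditional on transfection.
    p_inv, p_del, p_perfect : outcome probabilities conditional on both sites
        being cut; the remainder re-ligates with indel scars at one or both
        junctions.
    p_indel_single : probability that a resolved single cut leaves an indel
        scar rather than repairing perfectly; also the per-junction scar
        probability in the both-cut re-ligation channel (conditioned on at
        least one scar, else the allele would be in the perfect channel).
    indel_size_dist : categorical over signed indel sizes at cut sites.
    junction_insert_dist : categorical over insertion lengths (0-200 bp) at
        inversion/deletion junctions.
    """

    p_transfect: float = 0.5
    p_cut_fixed: float = 0.35
    p_cut_var: float = 0.35
    p_inv: float = 0.05
    p_del: float = 0.20
    p_perfect: float = 0.25
    p_indel_single: float = 0.5
    indel_size_dist: dict[int, float] = field(default_factory=default_indel_size_dist)
    junction_insert_dist: dict[int, float] = field(
        default_factory=default_junction_insert_dist
    )
    ploidy: int = 2

    def __post_init__(self) -> None:
        for name in (
            "p_transfect",
            "p_cut_fixed",
            "p_cut_var",
            "p_inv",
            "p_del",
            "p_perfect",
            "p_indel_single",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_inv + self.p_del + self.p_perfect > 1.0 + 1e-12:
            raise ValueError("p_inv + p_del + p_perfect must be <= 1")
        _validate_dist(self.indel_size_dist, "indel_size_dist")
        _validate_dist(self.junction_insert_dist, "junction_insert_dist")
        if any(k == 0 for k in self.indel_size_dist):
            raise ValueError("indel_size_dist must not contain size 0")
        if any(k < 0 or k > 200 for k in self.junction_insert_dist):
            raise ValueError("junction_insert_dist support must lie in 0..200")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass
class AlleleTruth:
    """Ground-truth allele population of one simulated sample.

    ``counts`` holds the six allele classes; ``edited`` has one row per
    non-wild-type allele with its drawn scar sizes/sequences and junction
    inserts, so read emission reproduces the same molecular structure every
    time an allele is sampled.
    """

    n_cells: int
    ploidy: int
    seed: int
    counts: dict[str, int]
    edited: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts) != set(ALLELE_CLASSES):
            raise ValueError(f"counts must have exactly the classes {ALLELE_CLASSES}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative allele class count")
        if sum(self.counts.values()) != self.ploidy * self.n_cells:
            raise ValueError("allele class counts must sum to ploidy * n_cells")
        n_edited = sum(v for k, v in self.counts.items() if k != "wild_type")
        if len(self.edited) != n_edited:
            raise ValueError("edited table inconsistent with class counts")

    @property
    def n_alleles(self) -> int:
        return self.ploidy * self.n_cells

    def fraction(self, label: str) -> float:
        return self.counts[label] / self.n_alleles

    @property
    def junction_carrier_fraction(self) -> float:
        """Fraction of alleles carrying an inversion junction (cdPCR target)."""
        return self.fraction("inversion")

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "ploidy": self.ploidy,
            "seed": self.seed,
            "counts": dict(self.counts),
        }


def _draw_edited_rows(
    label: str, n: int, model: OutcomeModel, rng: np.random.Generator
) -> list[list]:
    """Draw scar sizes / junction inserts for n alleles of one edited class."""
    rows: list[list] = []
    if n == 0:
        return rows
    if label in ("indel_fixed_only", "indel_var_only", "indel_both"):
        fix = _draw(model.indel_size_dist, rng, n) if label != "indel_var_only" else np.zeros(n, int)
        var = _draw(model.indel_size_dist, rng, n) if label != "indel_fixed_only" else np.zeros(n, int)
        for i in range(n):
            fs = _random_seq(fix[i], rng) if fix[i] > 0 else ""
            vs = _random_seq(var[i], rng) if var[i] > 0 else ""
            rows.append([label, int(fix[i]), fs, int(var[i]), vs, "", ""])
    elif label == "inversion":
        left = _draw(model.junction_insert_dist, rng, n)
        right = _draw(model.junction_insert_dist, rng, n)
        for i in range(n):
            rows.append(
                [label, 0, "", 0, "", _random_seq(left[i], rng), _random_seq(right[i], rng)]
            )
    elif label == "deletion":
        ins = _draw(model.junction_insert_dist, rng, n)
        for i in range(n):
            rows.append([label, 0, "", 0, "", _random_seq(ins[i], rng), ""])
    else:  # pragma: no cover - guarded by caller
        raise ValueError(label)
    return rows


def _build_edited(counts: dict[str, int], model: OutcomeModel, rng) -> pd.DataFrame:
    rows: list[list] = []
    for label in ("indel_fixed_only", "indel_var_only", "indel_both", "inversion", "deletion"):
        rows.extend(_draw_edited_rows(label, counts[label], model, rng))
    return pd.DataFrame(rows, columns=list(EDITED_COLUMNS))


def simulate_sample(
    locus: LocusPair, model: OutcomeModel, n_cells: int, seed: int
) -> AlleleTruth:
    """Simulate the allele population of one transfected sample.

    Transfection is drawn per cell; cutting and repair are drawn
    independently per allele of transfected cells. Deterministic given seed.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    n_transfected = int(rng.binomial(n_cells, model.p_transfect))
    n_t = model.ploidy * n_transfected
    n_alleles = model.ploidy * n_cells

    cut_f = rng.random(n_t) < model.p_cut_fixed
    cut_v = rng.random(n_t) < model.p_cut_var
    both = cut_f & cut_v
    single_f = cut_f & ~cut_v
    single_v = ~cut_f & cut_v

    counts = {k: 0 for k in ALLELE_CLASSES}

    # both-cut alleles: inversion / deletion / perfect / scarred re-ligation
    n_both = int(both.sum())
    u = rng.random(n_both)
    n_inv = int((u < model.p_inv).sum())
    n_del = int(((u >= model.p_inv) & (u < model.p_inv + model.p_del)).sum())
    thr = model.p_inv + model.p_del + model.p_perfect
    n_perfect = int(((u >= model.p_inv + model.p_del) & (u < thr)).sum())
    n_relig = n_both - n_inv - n_del - n_perfect
    q = model.p_indel_single
    w = np.array([q * (1 - q), (1 - q) * q, q * q])
    if w.sum() == 0:  # q==0 or 1: scars must land somewhere; default to both
        w = np.array([0.0, 0.0, 1.0]) if q == 1.0 else np.array([0.5, 0.5, 0.0])
    combo = rng.choice(3, size=n_relig, p=w / w.sum())
    counts["inversion"] = n_inv
    counts["deletion"] = n_del
    counts["indel_fixed_only"] += int((combo == 0).sum())
    counts["indel_var_only"] += int((combo == 1).sum())
    counts["indel_both"] = int((combo == 2).sum())

    # single-cut alleles: perfect vs scarred repair
    scar_f = int((rng.random(int(single_f.sum())) < model.p_indel_single).sum())
    scar_v = int((rng.random(int(single_v.sum())) < model.p_indel_single).sum())
    counts["indel_fixed_only"] += scar_f
    counts["indel_var_only"] += scar_v

    n_edited = sum(v for k, v in counts.items() if k != "wild_type")
    counts["wild_type"] = n_alleles - n_edited

    edited = _build_edited(counts, model, rng)
    return AlleleTruth(n_cells=n_cells, ploidy=model.ploidy, seed=seed, counts=counts, edited=edited)


def truth_from_counts(
    counts: dict[str, int],
    model: OutcomeModel,
    seed: int,
    ploidy: int | None = None,
) -> AlleleTruth:
    """Build a ground-truth population with exact class counts.

    Scar sizes and junction inserts are still drawn from the model; only the
    class composition is fixed. Total alleles must divide by ploidy.
    """
    ploidy = ploidy if ploidy is not None else model.ploidy
    full = {k: int(counts.get(k, 0)) for k in ALLELE_CLASSES}
    total = sum(full.values())
    if total == 0 or total % ploidy:
        raise ValueError("total allele count must be a positive multiple of ploidy")
    rng = np.random.default_rng(seed)
    edited = _build_edited(full, model, rng)
    return AlleleTruth(
        n_cells=total // ploidy, ploidy=ploidy, seed=seed, counts=full, edited=edited
    )


# ---------------------------------------------------------------------------
# cdPCR droplet panel emission


@dataclass(frozen=True)
class DropletNoise:
    """Fluorescence/validity noise model for simulated droplet panels."""

    bg_mean: float = 500.0
    bg_sd: float = 60.0
    pos_mean: float = 5000.0
    pos_sd: float = 250.0
    invalid_fraction: float = 0.04

    def __post_init__(self) -> None:
        if self.bg_sd < 0 or self.pos_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1)")


def emit_droplet_panel(
    truth: AlleleTruth,
    dna_mass_g: float,
    loaded_vol_ul: float = 25.0,
    droplet_vol_nl: float = 0.59,
    n_droplets: int = 25_000,
    noise: DropletNoise | None = None,
    seed: int = 0,
    occupancy: str = "poisson",
) -> tuple[pd.DataFrame, dict]:
    """Partition the sample's genome copies into droplets and image them.

    The DNA mass implies the loaded genome copies; each droplet captures
    genomes at rate lambda = copies * droplet_vol / loaded_vol (Poisson by
    default; ``occupancy="multinomial"`` scatters exactly ``round(copies)``
    molecules over droplets instead). Droplets holding >= 1 inversion-junction
    genome fluoresce high in both probe channels; all others emit background.
    A configurable fraction of droplets is flagged volume-invalid.

    Returns the droplet table (droplet_id, volume_nl, ch1, ch2, valid) and a
    per-panel truth dict for estimator-recovery checks.
    """
    noise = noise or DropletNoise()
    if dna_mass_g < 0 or loaded_vol_ul <= 0 or droplet_vol_nl <= 0:
        raise ValueError("mass and volumes must be non-negative/positive")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if droplet_vol_nl * n_droplets > loaded_vol_ul * 1000.0 + 1e-9:
        raise ValueError("total droplet volume exceeds loaded volume")
    rng = np.random.default_rng(seed)
    copies = genome_copies(dna_mass_g)
    f = truth.junction_carrier_fraction
    lam = copies * droplet_vol_nl / (loaded_vol_ul * 1000.0)

    if occupancy == "poisson":
        k_inv = rng.poisson(lam * f, size=n_droplets)
    elif occupancy == "multinomial":
        n_mol = int(round(copies))
        n_inv_mol = int(rng.binomial(n_mol, f)) if n_mol else 0
        # each molecule lands in a given droplet w.p. droplet_vol/loaded_vol
        p_drop = droplet_vol_nl / (loaded_vol_ul * 1000.0)
        probs = np.full(n_droplets + 1, p_drop)
        probs[-1] = 1.0 - p_drop * n_droplets  # dead volume
        placed = rng.multinomial(n_inv_mol, probs)
        k_inv = placed[:-1]
    else:
        raise ValueError(f"unknown occupancy model {occupancy!r}")

    positive = k_inv > 0
    n = n_droplets

    def channel() -> np.ndarray:
        bg = rng.normal(noise.bg_mean, noise.bg_sd, size=n)
        hi = rng.normal(noise.pos_mean, noise.pos_sd, size=n)
        return np.where(positive, hi, bg)

    ch1 = channel()
    ch2 = channel()
    valid = rng.random(n) >= noise.invalid_fraction
    volume = np.full(n, droplet_vol_nl)
    n_bad = int((~valid).sum())
    if n_bad:
        volume[~valid] = droplet_vol_nl * rng.uniform(0.5, 1.6, size=n_bad)
    panel = pd.DataFrame(
        {
            "droplet_id": np.arange(n),
            "volume_nl": volume,
            "ch1": ch1,
            "ch2": ch2,
            "valid": valid,
        }
    )
    panel_truth = {
        "genome_copies_loaded": copies,
        "carrier_fraction": f,
        "lambda_per_droplet": lam,
        "n_positive_droplets": int(positive.sum()),
        "n_positive_valid": int((positive & valid).sum()),
    }
    return panel, panel_truth


# ---------------------------------------------------------------------------
# read emission


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing-simulation settings shared by short and long reads.

    ``read_length`` sets the short-amplicon window (centred on the cut);
    error rates are per base. ``rearranged_dropout`` controls whether
    inversion/deletion alleles yield product for the wild-type-orientation
    short-amplicon primer pairs (they span a junction, so by default they do
    not — a documented bias knob). ``long_read_ceiling_bp`` bounds the
    inter-cut interval amenable to long-amplicon simulation.
    """

    coverage: int = 10_000
    read_length: int = 200
    substitution_error_rate: float = 0.001
    indel_error_rate: float = 1e-4
    seed: int = 0
    rearranged_dropout: bool = True
    long_read_ceiling_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 20:
            raise ValueError("read_length too short")
        for r in (self.substitution_error_rate, self.indel_error_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    seq: str
    label: str
    site_indel: int = 0


_OTHER_BASE = {b: DNA_ALPHABET.replace(b, "") for b in DNA_ALPHABET}


def _apply_errors(seq: str, cfg: ReadSimConfig, rng: np.random.Generator) -> str:
    L = len(seq)
    n_sub = rng.binomial(L, cfg.substitution_error_rate) if cfg.substitution_error_rate else 0
    n_ind = rng.poisson(cfg.indel_error_rate * L) if cfg.indel_error_rate else 0
    if not n_sub and not n_ind:
        return seq
    s = list(seq)
    if n_sub:
        for pos in rng.choice(L, size=min(n_sub, L), replace=False):
            s[pos] = _OTHER_BASE.get(s[pos], "ACG")[rng.integers(3)]
    for _ in range(n_ind):
        pos = int(rng.integers(len(s)))
        if rng.random() < 0.5 and len(s) > 1:
            del s[pos]
        else:
            s.insert(pos, DNA_ALPHABET[rng.integers(4)])
    return "".join(s)


def _apply_scar(seq: str, cut: int, size: int, ins_seq: str) -> str:
    """Apply an indel scar at 0-based split index ``cut`` of ``seq``."""
    if size == 0:
        return seq
    if size > 0:
        return seq[:cut] + ins_seq + seq[cut:]
    d = -size
    left = d // 2 + d % 2  # deletion straddles the cut, extra base on the left
    start = max(cut - left, 0)
    return seq[:start] + seq[start + d :]


def _rearranged_product(locus: LocusPair, row: pd.Series) -> tuple[str, int, int]:
    """Full product sequence for an inversion/deletion allele.

    Returns (product, left_junction_pos, right_junction_pos) with 0-based
    split indices of the junctions in product coordinates (for deletions the
    two coincide).
    """
    seg = locus.ref_segment
    a, b = locus.left_cut, locus.right_cut
    if row["label"] == "inversion":
        ins_l, ins_r = row["ins_left_seq"], row["ins_right_seq"]
        product = seg[:a] + ins_l + revcomp(seg[a:b]) + ins_r + seg[b:]
        left_j = a
        right_j = a + len(ins_l) + (b - a) + len(ins_r)
        return product, left_j, right_j
    if row["label"] == "deletion":
        ins = row["ins_left_seq"]
        product = seg[:a] + ins + seg[b:]
        return product, a, a + len(ins)
    raise ValueError(row["label"])


def _allele_product(locus: LocusPair, label: str, row: pd.Series | None) -> str:
    """Full-interval molecule for any allele class."""
    seg = locus.ref_segment
    if label == "wild_type":
        return seg
    assert row is not None
    if label in ("inversion", "deletion"):
        return _rearranged_product(locus, row)[0]
    # indel classes: apply scars right-to-left so coordinates stay valid
    cuts = [(locus.fixed_cut_pos, int(row["indel_fixed"]), row["indel_fixed_seq"]),
            (locus.variable_cut_pos, int(row["indel_var"]), row["indel_var_seq"])]
    out = seg
    for cut, size, ins in sorted(cuts, reverse=True):
        out = _apply_scar(out, cut, size, ins)
    return out


def amplicon_reference(
    locus: LocusPair, site: str, cfg: ReadSimConfig | None = None
) -> tuple[str, int]:
    """Reference short-amplicon window for a site and its 1-based cut position."""
    cfg = cfg or ReadSimConfig()
    cut = locus.fixed_cut_pos if site == "fixed" else locus.variable_cut_pos
    half = cfg.read_length // 2
    if cut - half < 0 or cut + half > len(locus.ref_segment):
        raise ValueError("amplicon window extends past ref_segment")
    return locus.ref_segment[cut - half : cut + half], half


def _class_probs(counts: dict[str, int], classes: list[str]) -> np.ndarray:
    w = np.array([counts[c] for c in classes], dtype=float)
    total = w.sum()
    if total == 0:
        raise ValueError("no amplifiable alleles to sample reads from")
    return w / total


def emit_amplicon_reads(
    truth: AlleleTruth, locus: LocusPair, site: str, cfg: ReadSimConfig | None = None
) -> list[SimRead]:
    """Emit short amplicon reads around one cut site.

    Reads are drawn from allele classes proportionally to their counts; each
    read from an indel allele reuses that allele's stored scar, so repeated
    sampling of one allele is molecularly consistent. With the default
    ``rearranged_dropout`` the inversion/deletion alleles produce no product
    (their junctions disrupt a wild-type-orientation primer pair); switching
    it off emits the junction-spanning product window instead.
    """
    if site not in ("fixed", "variable"):
        raise ValueError("site must be 'fixed' or 'variable'")
    cfg = cfg or ReadSimConfig()
    rng = np.random.default_rng(cfg.seed)
    ref_amp, half = amplicon_reference(locus, site, cfg)
    cut = locus.fixed_cut_pos if site == "fixed" else locus.variable_cut_pos

    classes = ["wild_type", "indel_fixed_only", "indel_var_only", "indel_both"]
    if not cfg.rearranged_dropout:
        classes += ["inversion", "deletion"]
    probs = _class_probs(truth.counts, classes)
    draws = rng.choice(len(classes), size=cfg.coverage, p=probs)

    by_label = {
        lab: truth.edited.index[truth.edited["label"] == lab].to_numpy()
        for lab in classes
        if lab != "wild_type"
    }
    indel_col = "indel_fixed" if site == "fixed" else "indel_var"
    seq_col = "indel_fixed_seq" if site == "fixed" else "indel_var_seq"
    product_cache: dict[int, str] = {}

    reads: list[SimRead] = []
    for i, ci in enumerate(draws):
        label = classes[ci]
        scar = 0
        if label == "wild_type":
            seq = ref_amp
        elif label in ("inversion", "deletion"):
            idxs = by_label[label]
            ridx = int(idxs[rng.integers(len(idxs))])
            if ridx not in product_cache:
                row = truth.edited.loc[ridx]
                product, left_j, right_j = _rearranged_product(locus, row)
                jc = left_j if cut == locus.left_cut else right_j
                product_cache[ridx] = product[max(jc - half, 0) : jc + half]
            seq = product_cache[ridx]
        else:
            idxs = by_label[label]
            ridx = int(idxs[rng.integers(len(idxs))])
            row = truth.edited.loc[ridx]
            scar = int(row[indel_col])
            seq = _apply_scar(ref_amp, half, scar, row[seq_col])
        seq = _apply_errors(seq, cfg, rng)
        reads.append(SimRead(read_id=f"{site}_read_{i}", seq=seq, label=label, site_indel=scar))
    return reads


def emit_long_reads(
    truth: AlleleTruth, locus: LocusPair, cfg: ReadSimConfig | None = None
) -> list[SimRead]:
    """Emit full-interval long amplicon reads for every allele class.

    Each read is the complete molecule between the outer primers (wild-type
    order, inverted internal segment with its junction inserts, or the fused
    deletion product), in random orientation, with sequencing errors applied.
    """
    cfg = cfg or ReadSimConfig()
    if locus.interval_bp > cfg.long_read_ceiling_bp:
        raise LongReadUnsupportedError(
            f"long-read simulation unsupported for this interval "
            f"({locus.interval_bp} bp > ceiling {cfg.long_read_ceiling_bp} bp)"
        )
    rng = np.random.default_rng(cfg.seed)
    classes = [c for c in ALLELE_CLASSES]
    probs = _class_probs(truth.counts, classes)
    draws = rng.choice(len(classes), size=cfg.coverage, p=probs)
    by_label = {
        lab: truth.edited.index[truth.edited["label"] == lab].to_numpy()
        for lab in classes
        if lab != "wild_type"
    }
    product_cache: dict[int, str] = {}
    reads: list[SimRead] = []
    for i, ci in enumerate(draws):
        label = classes[ci]
        if label == "wild_type":
            seq = locus.ref_segment
        else:
            idxs = by_label[label]
            ridx = int(idxs[rng.integers(len(idxs))])
            if ridx not in product_cache:
                product_cache[ridx] = _allele_product(
                    locus, label, truth.edited.loc[ridx]
                )
            seq = product_cache[ridx]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        seq = _apply_errors(seq, cfg, rng)
        reads.append(SimRead(read_id=f"long_read_{i}", seq=seq, label=label))
    return reads
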