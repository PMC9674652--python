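"""Synthetic selection-assay generator.

Emulates the data-generating process the scoring pipeline assumes: designed
variants enter the selection pool at Dirichlet-distributed input frequencies,
selection enriches each variant exponentially in its true nucleation score
(NS), biological replicates add log-normal noise, technical replicates are
multinomial resamples at fixed sequencing depth, and (optionally) counted
molecules are emitted as overlapping 125 bp paired-end reads with per-base
errors and Phred qualities.

True scores are drawn from a three-component (decrease / null / increase)
Gaussian mixture whose weights depend on mutation class and on whether the
variant touches only the polar N-terminal region (residues 1-28) or the
aliphatic C-terminal core (29-42); the defaults qualitatively mirror the
published regional structure of the amyloid-beta map, including a hotspot of
nucleation-promoting internal deletions around the centre of the peptide.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .library import (
    INSERTION,
    MULTI_DELETION,
    SINGLE_DELETION,
    SUBSTITUTION,
    TRUNCATION,
    DesignedLibrary,
    DesignedVariant,
)

NTERM_END = 28  # last residue of the polar N-terminal region

#: constant amplicon flanks (synthetic stand-ins; lengths match the assay design)
DEFAULT_FLANK5 = "ACTTTAAGAAGGAGATATACCATGG"  # 25 nt
DEFAULT_FLANK3 = "TAAGGATCCGAGCTCGCTTGG"  # 21 nt

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EffectMixture:
    """Three-component Gaussian mixture for true NS: (decrease, null, increase)."""

    weights: tuple[float, float, float]
    means: tuple[float, float, float] = (-3.0, 0.0, 1.5)
    sds: tuple[float, float, float] = (1.2, 0.15, 0.5)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")


def _default_effects() -> dict[tuple[str, str], EffectMixture]:
    """Per (mutation class, region) mixtures matching the published regional
    frequencies of nucleation-increasing / -decreasing variants at FDR 0.1."""
    return {
        (SUBSTITUTION, "nterm"): EffectMixture((0.26, 0.56, 0.18)),
        (SUBSTITUTION, "cterm"): EffectMixture((0.76, 0.18, 0.06)),
        (INSERTION, "nterm"): EffectMixture((0.30, 0.58, 0.12)),
        (INSERTION, "cterm"): EffectMixture((0.76, 0.19, 0.05)),
        (SINGLE_DELETION, "nterm"): EffectMixture((0.11, 0.70, 0.19)),
        (SINGLE_DELETION, "cterm"): EffectMixture((1.0, 0.0, 0.0)),
        (MULTI_DELETION, "nterm"): EffectMixture((0.19, 0.66, 0.15)),
        (MULTI_DELETION, "cterm"): EffectMixture((0.94, 0.05, 0.01)),
        (TRUNCATION, "nterm"): EffectMixture((0.0, 0.50, 0.50)),
        (TRUNCATION, "cterm"): EffectMixture((0.97, 0.03, 0.0)),
    }


@dataclass
class SimulationConfig:
    """Distributions, replicate structure, depths and seeds for the generator."""

    effects: dict[tuple[str, str], EffectMixture] = field(default_factory=_default_effects)
    #: internal deletions whose (first, last) removed positions fall in this box
    #: get the hotspot mixture instead of their regional one
    hotspot_box: tuple[tuple[int, int], tuple[int, int]] | None = ((17, 23), (22, 27))
    hotspot_mixture: EffectMixture = field(
        default_factory=lambda: EffectMixture((0.03, 0.02, 0.95))
    )
    dirichlet_alpha: float = 50.0
    n_bio: int = 3
    n_tech: int = 5
    sigma_rep: float = 0.1
    depth: int = 1_000_000
    dead_prob: float = 0.003
    err_rate: float = 0.0
    q_high: int = 37
    q_low: int = 20
    q_low_prob: float = 0.05
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    seed: int = 0

    def validate(self) -> None:
        for key, mix in self.effects.items():
            if key[0] not in (
                SUBSTITUTION, INSERTION, SINGLE_DELETION, MULTI_DELETION, TRUNCATION
            ) or key[1] not in ("nterm", "cterm"):
                raise ValueError(f"unknown effect cell {key!r}")
            mix.__post_init__()
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.sigma_rep < 0:
            raise ValueError("sigma_rep must be >= 0")

    def null(self) -> "SimulationConfig":
        """A copy with every variant's true NS identically zero."""
        null_mix = EffectMixture((0.0, 1.0, 0.0), sds=(1.2, 0.0, 0.5))
        return replace(
            self,
            effects={k: null_mix for k in self.effects},
            hotspot_mixture=null_mix,
            dead_prob=0.0,
        )


def variant_region(variant: DesignedVariant, nterm_end: int = NTERM_END) -> str:
    """'nterm' if the variant only touches residues 1..nterm_end, else 'cterm'.

    Insertions are judged by the position of the inserted residue; the gap
    between the two regions (inserted position nterm_end+1) counts as
    N-terminal, matching how the assay reports it.
    """
    spec = variant.specs[0]
    if spec.mclass == SUBSTITUTION or spec.mclass == SINGLE_DELETION:
        return "nterm" if spec.params[0] <= nterm_end else "cterm"
    if spec.mclass == INSERTION:
        return "nterm" if spec.params[0] <= nterm_end + 1 else "cterm"
    return "nterm" if max(_removed(variant)) <= nterm_end else "cterm"


def _removed(variant: DesignedVariant) -> tuple[int, ...]:
    spec = variant.specs[0]
    if spec.mclass == SINGLE_DELETION:
        return (spec.params[0],)
    if spec.mclass == MULTI_DELETION:
        return tuple(range(spec.params[0], spec.params[1] + 1))
    if spec.mclass == TRUNCATION:
        a, b = spec.params
        wt_len = len(variant.canonical_seq) + a + b
        return tuple(range(1, a + 1)) + tuple(range(wt_len - b + 1, wt_len + 1))
    raise ValueError(f"no removed positions for class {spec.mclass}")


def sample_true_scores(
    library: DesignedLibrary,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one true NS (and a dead flag) per designed variant.

    Returns a frame with columns variant_id, ns_true, component (the mixture
    component the draw came from), dead; the WT has ns_true 0, component
    'null' and is never dead.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    comp_names = ("neg", "null", "pos")
    rows = []
    for v in library:
        if v.is_wt:
            rows.append((v.variant_id, 0.0, "null", False))
            continue
        mix = _mixture_for(v, cfg)
        comp = rng.choice(3, p=mix.weights)
        ns = rng.normal(mix.means[comp], mix.sds[comp])
        dead = bool(rng.random() < cfg.dead_prob)
        rows.append((v.variant_id, ns, comp_names[comp], dead))
    return pd.DataFrame(rows, columns=["variant_id", "ns_true", "component", "dead"])


def _mixture_for(variant: DesignedVariant, cfg: SimulationConfig) -> EffectMixture:
    spec = variant.specs[0]
    if (
        cfg.hotspot_box is not None
        and spec.mclass == MULTI_DELETION
        and cfg.hotspot_box[0][0] <= spec.params[0] <= cfg.hotspot_box[0][1]
        and cfg.hotspot_box[1][0] <= spec.params[1] <= cfg.hotspot_box[1][1]
    ):
        return cfg.hotspot_mixture
    key = (spec.mclass if not variant.is_wt else SUBSTITUTION, variant_region(variant))
    try:
        return cfg.effects[key]
    except KeyError as exc:
        raise KeyError(f"no effect mixture configured for cell {key!r}") from exc


def simulate_counts(
    library: DesignedLibrary,
    effects: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the replicate count table implied by the true scores.

    Per biological replicate: input frequencies are a Dirichlet draw with
    concentration ``dirichlet_alpha``; output frequencies are proportional to
    f_in * exp(ns_true + eps) with eps ~ N(0, sigma_rep^2) drawn once per
    (variant, biological replicate); dead variants are zeroed before
    renormalization. Each technical replicate is an independent multinomial
    of size ``depth`` from its biological replicate's frequencies.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    eff = effects.set_index("variant_id")
    ids = [v.variant_id for v in library]
    ns_true = eff.loc[ids, "ns_true"].to_numpy(float)
    dead = eff.loc[ids, "dead"].to_numpy(bool)
    n = len(ids)
    if dead.all():
        raise ValueError("degenerate simulation: every variant is dead")

    frames = []
    for b in range(1, cfg.n_bio + 1):
        f_in = rng.dirichlet(np.full(n, cfg.dirichlet_alpha))
        eps = rng.normal(0.0, cfg.sigma_rep, n) if cfg.sigma_rep > 0 else np.zeros(n)
        w = f_in * np.exp(ns_true + eps)
        w[dead] = 0.0
        f_out = w / w.sum()
        for t in range(1, cfg.n_tech + 1):
            cin = rng.multinomial(cfg.depth, f_in)
            cout = rng.multinomial(cfg.depth, f_out)
            frames.append(
                pd.DataFrame(
                    {
                        "variant_id": ids,
                        "bio_rep": b,
                        "tech_rep": t,
                        "count_in": cin,
                        "count_out": cout,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    library: DesignedLibrary,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: (true effects, count table) under one seed."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    effects = sample_true_scores(library, cfg, rng)
    counts = simulate_counts(library, effects, cfg, rng)
    return effects, counts


# ---------------------------------------------------------------------------
# FASTQ emission


def _open_write(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def emit_fastq(
    counts: pd.DataFrame,
    library: DesignedLibrary,
    outdir: str | Path,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    gzipped: bool = False,
) -> pd.DataFrame:
    """Write one paired FASTQ file pair per (bio_rep, tech_rep, role) sample.

    Every counted molecule becomes one read pair covering the construct
    flank5 + variant nt sequence + flank3 from both ends (read length 125 nt,
    shorter when the construct is shorter). With ``err_rate`` zero, reads are
    error-free with uniform high qualities; otherwise qualities follow the
    two-state Q_high/Q_low model and per-base errors occur at ``err_rate`` on
    average, concentrated on low-quality bases in proportion to 10^(-Q/10).

    Returns a sample sheet frame (sample, bio_rep, tech_rep, role, r1, r2).
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nt = {v.variant_id: v.nt_seq for v in library}
    max_len = max(len(s) for s in nt.values()) + len(cfg.flank5) + len(cfg.flank3)
    if max_len > 250:
        raise ValueError(
            f"construct length {max_len} exceeds paired 125 bp read coverage (250)"
        )
    suffix = ".fastq.gz" if gzipped else ".fastq"
    sheet = []
    for (b, t), sub in counts.groupby(["bio_rep", "tech_rep"]):
        for role, col in (("input", "count_in"), ("output", "count_out")):
            sample = f"bio{b}_tech{t}_{role}"
            r1_path = outdir / f"{sample}_R1{suffix}"
            r2_path = outdir / f"{sample}_R2{suffix}"
            _emit_sample(sub, nt, col, sample, r1_path, r2_path, cfg, rng)
            sheet.append((sample, b, t, role, str(r1_path), str(r2_path)))
    return pd.DataFrame(
        sheet, columns=["sample", "bio_rep", "tech_rep", "role", "r1", "r2"]
    )


def _emit_sample(sub, nt, col, sample, r1_path, r2_path, cfg, rng) -> None:
    pairs: list[tuple[str, str, str, str]] = []
    for vid, c in zip(sub["variant_id"], sub[col]):
        c = int(c)
        if c == 0:
            continue
        construct = cfg.flank5 + nt[vid] + cfg.flank3
        r1 = construct[:125]
        r2 = revcomp(construct)[:125]
        for _ in range(c):
            s1, q1 = _noisy_read(r1, cfg, rng)
            s2, q2 = _noisy_read(r2, cfg, rng)
            pairs.append((s1, q1, s2, q2))
    order = rng.permutation(len(pairs))
    with _open_write(r1_path) as f1, _open_write(r2_path) as f2:
        for serial, i in enumerate(order):
            s1, q1, s2, q2 = pairs[i]
            f1.write(f"@{sample}:{serial}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{sample}:{serial}/2\n{s2}\n+\n{q2}\n")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _noisy_read(seq: str, cfg: SimulationConfig, rng) -> tuple[str, str]:
    m = len(seq)
    if cfg.err_rate == 0.0:
        return seq, chr(cfg.q_high + 33) * m
    low = rng.random(m) < cfg.q_low_prob
    quals = np.where(low, cfg.q_low, cfg.q_high)
    # per-base error probability proportional to 10^(-Q/10), mean = err_rate
    p_raw = 10.0 ** (-quals / 10.0)
    mean_raw = cfg.q_low_prob * 10 ** (-cfg.q_low / 10) + (1 - cfg.q_low_prob) * 10 ** (
        -cfg.q_high / 10
    )
    p_err = np.minimum(1.0, cfg.err_rate * p_raw / mean_raw)
    hit = rng.random(m) < p_err
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if hit.any():
        idx = np.where(hit)[0]
        for i in idx:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    qual = (quals + 33).astype(np.uint8).tobytes().decode()
    return arr.tobytes().decode(), qual
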