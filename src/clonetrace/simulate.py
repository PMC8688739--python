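"""Ground-truthed simulation of a donor pool and post-BMT tissue repertoires.

The generator emulates the statistical design of a murine bone-marrow
transplant repertoire study: a single donor T-cell pool with power-law clone
frequencies is infused into syngeneic and allogeneic recipients; in
allogeneic recipients a small, recipient-specific subset of alloreactive
clones — drawn preferentially from the low-frequency tail of the pool —
expands by lognormal multipliers; each tissue of a recipient then observes a
Dirichlet-perturbed copy of the recipient-level clone distribution through a
finite multinomial template sample.

Consequences of this construction, mirroring the hallmarks the analysis is
built to detect:

* allogeneic samples concentrate template mass on few clones → fewer unique
  clones and higher clonality at equal depth;
* the expanded clones dominate every tissue of their recipient → high
  within-recipient cross-tissue overlap;
* each recipient activates its own random subset → little top-clone sharing
  between allogeneic recipients;
* expanded clones come from the pool tail → usually not detectable in a
  finite-depth sample of the pre-transplant graft (a sampling phenomenon,
  not a separate clone universe);
* alloreactive clones carry the "V26" label with elevated probability →
  template-weighted V26 usage is higher in the allogeneic group.

CDR3 amino-acid strings are generated as ``C`` + 8–16 random residues + ``F``
to look domain-plausible; no biological V(D)J recombination model is
attempted.  Nucleotide sequences are a fixed codon back-translation of the
amino acids, so NT and AA keys coincide on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repio import (
    CLONE_COLUMNS,
    D_UNRESOLVED,
    KeyMode,
    Repertoire,
    RepertoireSet,
    SampleMeta,
    write_manifest,
    write_rearrangement_table,
)

__all__ = [
    "SimConfig",
    "DonorPool",
    "RecipientSim",
    "Experiment",
    "LYMPHOID_TISSUES",
    "PARENCHYMAL_TISSUES",
    "simulate_donor_pool",
    "sample_repertoire",
    "simulate_recipient",
    "simulate_experiment",
    "write_experiment",
]

LYMPHOID_TISSUES = ("blood", "spleen", "pLN", "mLN")
PARENCHYMAL_TISSUES = ("liver", "lung", "gut", "skin")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# one fixed codon per residue: deterministic AA -> NT back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_CODON_TABLE = str.maketrans(_CODON)

# Baseline V-family usage of the naive donor pool.  V26 starts modest; its
# enrichment among alloreactive clones is what the analysis must recover.
BASE_V_USAGE = {
    "V1": 0.03, "V2": 0.05, "V3": 0.04, "V4": 0.06, "V5": 0.08,
    "V12": 0.07, "V13": 0.09, "V14": 0.04, "V15": 0.05, "V16": 0.06,
    "V17": 0.05, "V19": 0.07, "V20": 0.04, "V23": 0.03, "V24": 0.04,
    "V26": 0.04, "V29": 0.06, "V30": 0.03, "V31": 0.07,
}

BASE_J_USAGE = {
    "J1-1": 0.05, "J1-2": 0.07, "J1-3": 0.04, "J1-4": 0.06, "J1-5": 0.05,
    "J1-6": 0.09, "J2-1": 0.10, "J2-2": 0.06, "J2-3": 0.08, "J2-4": 0.07,
    "J2-5": 0.12, "J2-6": 0.05, "J2-7": 0.16,
}

BASE_D_USAGE = {"D1": 0.45, "D2": 0.35, D_UNRESOLVED: 0.20}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated transplant experiment.

    Frequencies of the donor pool follow ``rank^(-zipf_alpha)``.  Depths are
    template counts drawn per sample: lymphoid compartments (blood, spleen,
    pLN, mLN) are sampled more deeply than parenchymal GVHD target organs
    (liver, lung, gut, skin), reflecting their higher T-cell input.
    ``expansion_log_mean``/``expansion_log_sd`` parameterise the lognormal
    expansion multiplier of activated alloreactive clones (natural-log
    scale); the default median multiplier e^12 ≈ 1.6e5 carries a tail clone
    of frequency ~1e-6 to the percent range, the magnitude implied by top
    clones that are undetectable in the graft.  ``tissue_dirichlet_tau`` and
    ``recipient_jitter_tau`` are Dirichlet concentrations (larger = less
    resampling noise).  ``v26_bias`` multiplies the baseline V26 probability
    for alloreactive clones.  ``day14_log_boost`` compounds the expansion at
    the second time point when ``days`` includes 14.
    """

    n_clones: int = 50_000
    zipf_alpha: float = 1.3
    n_syn: int = 3
    n_allo: int = 3
    tissues: tuple[str, ...] = LYMPHOID_TISSUES + PARENCHYMAL_TISSUES
    depth_lymphoid: int = 30_000
    depth_parenchymal: int = 10_000
    donor_sample_depth: int = 20_000
    allo_fraction: float = 0.005
    expansion_log_mean: float = 12.0
    expansion_log_sd: float = 2.0
    activated_per_recipient: int = 50
    tissue_dirichlet_tau: float = 20_000.0
    recipient_jitter_tau: float = 200_000.0
    v26_bias: float = 10.0
    days: tuple[int, ...] = (7,)
    day14_log_boost: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_clones < 100:
            problems.append("n_clones must be >= 100")
        if self.zipf_alpha < 0:
            problems.append("zipf_alpha must be >= 0")
        for name in ("depth_lymphoid", "depth_parenchymal", "donor_sample_depth"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if not (0.0 < self.allo_fraction < 1.0):
            problems.append("allo_fraction must lie in (0, 1)")
        if self.activated_per_recipient < 1:
            problems.append("activated_per_recipient must be >= 1")
        if self.tissue_dirichlet_tau <= 0 or self.recipient_jitter_tau <= 0:
            problems.append("Dirichlet concentrations must be > 0")
        if self.v26_bias <= 0:
            problems.append("v26_bias must be > 0")
        if self.n_syn < 0 or self.n_allo < 0 or self.n_syn + self.n_allo < 1:
            problems.append("need at least one recipient")
        unknown = [t for t in self.tissues if t not in LYMPHOID_TISSUES + PARENCHYMAL_TISSUES]
        if unknown:
            problems.append(f"unknown tissues {unknown}")
        bad_days = [d for d in self.days if d not in (7, 14)]
        if bad_days:
            problems.append(f"days must be a subset of (7, 14), got {bad_days}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def depth_for(self, tissue: str) -> int:
        return self.depth_lymphoid if tissue in LYMPHOID_TISSUES else self.depth_parenchymal


@dataclass(frozen=True)
class DonorPool:
    """Latent ground truth: the graft's clone pool with true frequencies."""

    clones: pd.DataFrame  # cdr3_nt, cdr3_aa, v_gene, d_gene, j_gene, frequency, alloreactive

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def frequency(self) -> np.ndarray:
        return self.clones["frequency"].to_numpy()

    @property
    def alloreactive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.clones["alloreactive"].to_numpy())


@dataclass(frozen=True)
class RecipientSim:
    """One recipient's simulated tissues plus its latent expansion draw."""

    mouse_id: str
    group: str
    samples: dict[tuple[str, int], Repertoire]  # keyed by (tissue, day)
    activated_indices: np.ndarray
    multipliers: np.ndarray
    distribution: np.ndarray  # recipient-level clone distribution (day 7)

    def tissue(self, tissue: str, day: int = 7) -> Repertoire:
        return self.samples[(tissue, day)]


@dataclass(frozen=True)
class Experiment:
    """Full simulated experiment: recipients, donor pool and graft sample."""

    config: SimConfig
    pool: DonorPool
    donor_sample: Repertoire
    recipients: dict[str, RecipientSim]
    repertoires: RepertoireSet  # all recipient samples + the donor sample
    manifest: pd.DataFrame


def _random_cdr3(rng: np.random.Generator, n: int) -> list[str]:
    """n distinct CDR3 amino-acid strings of the form C + 8-16 residues + F."""
    letters = np.array(list(AA_ALPHABET))
    out: list[str] = []
    need = n
    while need > 0:
        lens = rng.integers(8, 17, size=need)
        codes = rng.integers(0, len(letters), size=int(lens.sum()))
        chars = letters[codes]
        pos = 0
        for L in lens:
            out.append("C" + "".join(chars[pos : pos + L]) + "F")
            pos += int(L)
        seen = set()
        uniq = []
        for s in out:
            if s not in seen:
                seen.add(s)
                uniq.append(s)
        out = uniq
        need = n - len(out)
    return out


def _biased_v26(base: Mapping[str, float], bias: float) -> np.ndarray:
    labels = list(base)
    p = np.array([base[v] for v in labels], dtype=float)
    i26 = labels.index("V26")
    p26 = min(p[i26] * bias, 0.9)
    scale = (1.0 - p26) / (1.0 - p[i26])
    p = p * scale
    p[i26] = p26
    return p / p.sum()


def simulate_donor_pool(config: SimConfig, rng: np.random.Generator | None = None) -> DonorPool:
    """Generate the latent graft pool.

    Frequencies follow ``rank^(-zipf_alpha)`` (uniform when alpha = 0);
    alloreactive clones are sampled without replacement with probability
    proportional to rank, i.e. preferentially from the low-frequency tail;
    alloreactive clones draw their V family from a V26-enriched distribution.
    Deterministic under a fixed seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_clones
    ranks = np.arange(1, n + 1, dtype=float)
    raw = ranks ** (-config.zipf_alpha)
    freq = raw / raw.sum()

    n_allo = max(1, round(config.allo_fraction * n))
    allo_idx = rng.choice(n, size=n_allo, replace=False, p=ranks / ranks.sum())
    alloreactive = np.zeros(n, dtype=bool)
    alloreactive[allo_idx] = True

    v_labels = np.array(list(BASE_V_USAGE))
    v_base_p = np.array(list(BASE_V_USAGE.values()))
    v = rng.choice(v_labels, size=n, p=v_base_p)
    v[alloreactive] = rng.choice(
        v_labels, size=int(alloreactive.sum()), p=_biased_v26(BASE_V_USAGE, config.v26_bias)
    )
    j = rng.choice(np.array(list(BASE_J_USAGE)), size=n, p=np.array(list(BASE_J_USAGE.values())))
    d = rng.choice(np.array(list(BASE_D_USAGE)), size=n, p=np.array(list(BASE_D_USAGE.values())))

    aa = _random_cdr3(rng, n)
    nt = [s.translate(_CODON_TABLE) for s in aa]

    clones = pd.DataFrame(
        {
            "cdr3_nt": nt,
            "cdr3_aa": aa,
            "v_gene": v,
            "d_gene": d,
            "j_gene": j,
            "frequency": freq,
            "alloreactive": alloreactive,
        }
    )
    return DonorPool(clones=clones)


def sample_repertoire(
    pool: DonorPool,
    depth: int,
    meta: SampleMeta,
    seed: int | np.random.Generator,
    frequencies: np.ndarray | None = None,
) -> Repertoire:
    """Multinomial template sample of ``depth`` templates from the pool.

    ``frequencies`` overrides the pool's true frequencies (e.g. a recipient-
    or tissue-level distribution); clones drawing zero templates are omitted.
    The resulting repertoire is collapsed under the AA key by construction
    (pool CDR3s are unique).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = pool.frequency if frequencies is None else np.asarray(frequencies, dtype=float)
    if p.shape != (pool.n_clones,) or (p < 0).any() or p.sum() <= 0:
        raise ValueError("frequencies must be a non-negative vector over the pool clones")
    counts = rng.multinomial(depth, p / p.sum())
    nz = np.flatnonzero(counts)
    df = pool.clones.iloc[nz][["cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene"]].copy()
    df["templates"] = counts[nz]
    return Repertoire(meta, df[list(CLONE_COLUMNS)], key=KeyMode.AA)


def _dirichlet_perturb(rng: np.random.Generator, p: np.ndarray, tau: float) -> np.ndarray:
    """Draw q ~ Dirichlet(tau * p); expectation p, noise shrinking with tau."""
    g = rng.gamma(shape=tau * p)
    s = g.sum()
    if s <= 0:  # pathological only for tiny tau; fall back to the mean
        return p
    return g / s


def simulate_recipient(
    pool: DonorPool,
    group: str,
    config: SimConfig,
    recipient_seed: int | np.random.SeedSequence,
    mouse_id: str = "m1",
) -> RecipientSim:
    """Simulate every tissue of one recipient.

    Allogeneic: a recipient-specific subset of ``activated_per_recipient``
    alloreactive clones receives lognormal expansion multipliers; the
    renormalised result is the recipient-level distribution.  Syngeneic: mild
    Dirichlet jitter of the pool frequencies only.  Each tissue then draws a
    Dirichlet-perturbed copy (concentration ``tissue_dirichlet_tau``) and a
    multinomial template sample at the tissue's depth.  Day-14 samples reuse
    the same activation draw with the expansion compounded by
    ``exp(day14_log_boost)``.
    """
    if group not in ("syngeneic", "allogeneic"):
        raise ValueError(f"unknown recipient group {group!r}")
    config.validate()
    rng = np.random.default_rng(recipient_seed)
    f = pool.frequency

    if group == "allogeneic":
        allo_idx = pool.alloreactive_indices
        k = min(config.activated_per_recipient, allo_idx.size)
        activated = np.sort(rng.choice(allo_idx, size=k, replace=False))
        multipliers = rng.lognormal(
            mean=config.expansion_log_mean, sigma=config.expansion_log_sd, size=k
        )
        base = f.copy()
        base[activated] *= multipliers
        base /= base.sum()
    else:
        activated = np.empty(0, dtype=int)
        multipliers = np.empty(0, dtype=float)
        base = _dirichlet_perturb(rng, f, config.recipient_jitter_tau)

    samples: dict[tuple[str, int], Repertoire] = {}
    for day in config.days:
        if day == 14 and group == "allogeneic" and activated.size:
            w = f.copy()
            w[activated] *= multipliers * np.exp(config.day14_log_boost)
            w /= w.sum()
        else:
            w = base
        for tissue in config.tissues:
            q = _dirichlet_perturb(rng, w, config.tissue_dirichlet_tau)
            meta = SampleMeta(
                sample_id=f"{mouse_id}_{tissue}_d{day}",
                mouse_id=mouse_id,
                group=group,
                tissue=tissue,
                day=day,
            )
            samples[(tissue, day)] = sample_repertoire(
                pool, config.depth_for(tissue), meta, rng, frequencies=q
            )
    return RecipientSim(
        mouse_id=mouse_id,
        group=group,
        samples=samples,
        activated_indices=activated,
        multipliers=multipliers,
        distribution=base,
    )


def simulate_experiment(config: SimConfig | None = None) -> Experiment:
    """Simulate the full design: donor pool, graft sample, all recipients.

    All randomness flows from ``config.seed`` through spawned child streams,
    so a fixed seed reproduces every table byte-for-byte.
    """
    if config is None:
        config = SimConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    pool_ss, donor_ss, *rec_ss = root.spawn(2 + config.n_syn + config.n_allo)

    pool = simulate_donor_pool(config, rng=np.random.default_rng(pool_ss))

    donor_meta = SampleMeta(
        sample_id="donor_graft",
        mouse_id="donor",
        group="donor_pretransplant",
        tissue="graft",
        day=0,
    )
    donor_sample = sample_repertoire(
        pool, config.donor_sample_depth, donor_meta, np.random.default_rng(donor_ss)
    )

    recipients: dict[str, RecipientSim] = {}
    mouse_specs = [("syn", i + 1, "syngeneic") for i in range(config.n_syn)] + [
        ("allo", i + 1, "allogeneic") for i in range(config.n_allo)
    ]
    for (prefix, i, group), ss in zip(mouse_specs, rec_ss):
        mouse_id = f"{prefix}{i}"
        recipients[mouse_id] = simulate_recipient(
            pool, group, config, ss, mouse_id=mouse_id
        )

    reps = [donor_sample]
    for rec in recipients.values():
        for day in config.days:
            for tissue in config.tissues:
                reps.append(rec.samples[(tissue, day)])
    repset = RepertoireSet(reps, key=KeyMode.AA)

    manifest = pd.DataFrame(
        [
            {
                "file": f"{r.sample_id}.tsv",
                "sample_id": r.sample_id,
                "mouse_id": r.meta.mouse_id,
                "group": r.meta.group,
                "tissue": r.meta.tissue,
                "day": r.meta.day,
            }
            for r in repset
        ]
    )
    return Experiment(
        config=config,
        pool=pool,
        donor_sample=donor_sample,
        recipients=recipients,
        repertoires=repset,
        manifest=manifest,
    )


def write_experiment(exp: Experiment, outdir: str | Path, dialect: str = "airr") -> Path:
    """Write one clone table per sample plus manifest and ground truth.

    Emits ``<sample>.tsv`` per sample, ``manifest.tsv``, and two ground-truth
    tables for parameter-recovery tests: ``ground_truth_pool.tsv`` (true
    frequencies and alloreactive flags) and ``ground_truth_activation.tsv``
    (per-recipient activated clones and multipliers).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rep in exp.repertoires:
        write_rearrangement_table(rep, outdir / f"{rep.sample_id}.tsv", dialect=dialect)
    write_manifest(exp.manifest, outdir / "manifest.tsv")
    exp.pool.clones.to_csv(outdir / "ground_truth_pool.tsv", sep="\t", index=False)
    act_rows = []
    for rec in exp.recipients.values():
        for idx, mult in zip(rec.activated_indices, rec.multipliers):
            act_rows.append(
                {
                    "mouse_id": rec.mouse_id,
                    "clone_index": int(idx),
                    "cdr3_aa": exp.pool.clones["cdr3_aa"].iloc[int(idx)],
                    "multiplier": float(mult),
                }
            )
    pd.DataFrame(
        act_rows, columns=["mouse_id", "clone_index", "cdr3_aa", "multiplier"]
    ).to_csv(outdir / "ground_truth_activation.tsv", sep="\t", index=False)
    return outdir
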