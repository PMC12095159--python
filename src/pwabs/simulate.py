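"""Seeded synthetic PWAbS cohorts with a ground-truth ledger.

The generator emulates the statistical structure a protein-array autoantibody
screen assumes: a lognormal reactivity background per subject x antigen,
group-specific multiplicative elevations for planted antigen sets, positive
and negative control spots with per-array jitter, sex imbalance across
diagnostic groups, and clinical traits drawn from group baselines with linear
coupling to designated driver antigens.

Latent truth lives on the AU (arbitrary-unit) scale; spot fluorescence is
back-computed as ``F = F_neg + AU/100 * (F_pos - F_neg)`` before
multiplicative measurement noise, so quantification inverts generation up to
noise and recovery is testable against the :class:`TruthLedger`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from zlib import crc32

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TraitSpec",
    "TruthLedger",
    "SimConfigError",
    "generate_cohort",
    "generate_sequences",
    "default_trait_model",
    "write_fluorescence_tsv",
    "read_fluorescence_tsv",
    "AMINO_ACIDS",
    "MMSE_SUBSCALES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GROUPS = ("AD", "DLB", "CNI")

#: MMSE subscale -> maximum score (totals 30)
MMSE_SUBSCALES = {
    "Orientation_Time": 5,
    "Orientation_Space": 5,
    "Registration": 3,
    "Attention": 5,
    "Recall": 3,
    "Naming": 2,
    "Repetition": 1,
    "Comprehension": 3,
    "Reading": 1,
    "Writing": 1,
    "Drawing": 1,
}


class SimConfigError(ValueError):
    """A simulation parameter violates its stated bound."""


@dataclass
class TraitSpec:
    """One clinical trait: per-group (mean, sd) baselines, optional linear
    coupling to driver antigens, optional range clipping.

    ``drivers`` maps a driver reference to a coefficient on the driver
    antigen's standardized latent AU.  References are either an antigen id
    or one of ``"elevated_ad:<i>"``, ``"elevated_dlb:<i>"``,
    ``"elevated_shared:<i>"`` resolved against the planted sets at
    generation time.  Binary traits threshold the latent value at 0.5.
    """

    baselines: dict  # group -> (mean, sd)
    drivers: dict = field(default_factory=dict)  # ref -> coefficient
    bounds: tuple | None = None
    binary: bool = False
    integer: bool = False


def default_trait_model() -> dict:
    """Default clinical-trait model for an elderly memory-clinic cohort.

    MMSE and HDSR group baselines are the cohort's reported means/sd; the
    remaining traits use plausible geriatric-assessment defaults.  The MMSE
    memory subscales (Registration, Recall) and the MMSE total are coupled
    negatively to the first shared planted antigen, mimicking an
    autoantibody whose serum level tracks memory impairment.
    """
    sub = {}
    for name, mx in MMSE_SUBSCALES.items():
        sub[name] = TraitSpec(
            baselines={
                "AD": (mx * 20.2 / 30, mx / 4.5),
                "DLB": (mx * 21.1 / 30, mx / 4.0),
                "CNI": (mx * 28.9 / 30, mx / 9.0),
            },
            bounds=(0, mx),
        )
    sub["Recall"].drivers = {"elevated_shared:0": -0.8}
    sub["Registration"].drivers = {"elevated_shared:0": -0.6}
    model = {
        "MMSE": TraitSpec(
            baselines={"AD": (20.2, 3.9), "DLB": (21.1, 6.6), "CNI": (28.9, 1.4)},
            drivers={"elevated_shared:0": -2.0},
            bounds=(0, 30),
        ),
        "HDSR": TraitSpec(
            baselines={"AD": (19.9, 5.6), "DLB": (22.1, 5.6), "CNI": (27.9, 2.0)},
            bounds=(0, 30),
        ),
        "CGA7": TraitSpec(
            baselines={"AD": (4.5, 1.2), "DLB": (4.8, 1.3), "CNI": (6.5, 0.7)},
            drivers={"elevated_dlb:0": -0.5},
            bounds=(0, 7),
        ),
        "GDS15": TraitSpec(
            baselines={"AD": (5.0, 2.5), "DLB": (6.0, 3.0), "CNI": (2.5, 1.8)},
            bounds=(0, 15),
        ),
        "Barthel": TraitSpec(
            baselines={"AD": (85.0, 12.0), "DLB": (80.0, 15.0), "CNI": (97.0, 5.0)},
            bounds=(0, 100),
        ),
        "IADL": TraitSpec(
            baselines={"AD": (4.5, 2.0), "DLB": (4.0, 2.0), "CNI": (7.5, 0.8)},
            bounds=(0, 8),
        ),
        "back_pain": TraitSpec(
            baselines={"AD": (0.5, 0.3), "DLB": (0.5, 0.3), "CNI": (0.2, 0.3)},
            drivers={"elevated_shared:0": 0.3},
            binary=True,
        ),
        "n_comorbidities": TraitSpec(
            baselines={"AD": (3.0, 1.5), "DLB": (3.0, 1.5), "CNI": (2.0, 1.5)},
            bounds=(0, 12),
            integer=True,
        ),
    }
    model.update(sub)
    return model


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study cohort (18 AD / 8 DLB / 9 CNI; female
    fractions 82.4 / 62.5 / 33.3%) on a desk-scale 300-antigen panel with
    10 + 10 + 10 planted elevations; the full 13,455-clone panel is one
    ``n_antigens`` away.
    """

    n_ad: int = 18
    n_dlb: int = 8
    n_cni: int = 9
    n_antigens: int = 300
    n_pos_controls: int = 8
    n_neg_controls: int = 8
    background_log_mean: float = 1.0  # natural-log mean of baseline AU (~e^1 = 2.7 AU)
    background_log_sd: float = 0.8
    pos_control_level: float = 50_000.0  # fluorescence units
    neg_control_level: float = 500.0
    n_elev_ad_only: int = 10
    n_elev_dlb_only: int = 10
    n_elev_shared: int = 10
    effect_fold: float = 4.0
    measurement_cv: float = 0.1
    female_frac_ad: float = 0.824
    female_frac_dlb: float = 0.625
    female_frac_cni: float = 0.333
    age_range: tuple = (70.0, 90.0)
    trait_model: dict = field(default_factory=default_trait_model)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_ad", "n_dlb", "n_cni", "n_antigens", "n_pos_controls",
                     "n_neg_controls", "n_elev_ad_only", "n_elev_dlb_only", "n_elev_shared"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        n_planted = self.n_elev_ad_only + self.n_elev_dlb_only + self.n_elev_shared
        if n_planted > self.n_antigens:
            raise SimConfigError(
                f"planted antigen count {n_planted} exceeds panel size {self.n_antigens}"
            )
        if self.effect_fold <= 1:
            raise SimConfigError(f"effect_fold must be > 1, got {self.effect_fold}")
        if not (self.pos_control_level > self.neg_control_level >= 0):
            raise SimConfigError(
                "control levels must satisfy pos_control_level > neg_control_level >= 0, "
                f"got {self.pos_control_level} vs {self.neg_control_level}"
            )
        for name in ("female_frac_ad", "female_frac_dlb", "female_frac_cni"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {f}")
        if self.measurement_cv < 0:
            raise SimConfigError(f"measurement_cv must be >= 0, got {self.measurement_cv}")


@dataclass
class TruthLedger:
    """Ground truth behind a synthetic cohort, for recovery tests."""

    elevated_ad: set  # antigen ids elevated in AD (shared ids appear in both sets)
    elevated_dlb: set
    trait_drivers: dict  # trait -> {antigen_id: coefficient}
    latent_au: pd.DataFrame  # subjects x antigens, pre-noise AU

    @property
    def elevated_union(self) -> set:
        return self.elevated_ad | self.elevated_dlb

    def to_json(self, path) -> None:
        payload = {
            "elevated_ad": sorted(self.elevated_ad),
            "elevated_dlb": sorted(self.elevated_dlb),
            "trait_drivers": {t: dict(d) for t, d in self.trait_drivers.items()},
            "latent_au": json.loads(self.latent_au.to_json(orient="split")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        latent = pd.DataFrame(
            payload["latent_au"]["data"],
            index=payload["latent_au"]["index"],
            columns=payload["latent_au"]["columns"],
        )
        return cls(
            set(payload["elevated_ad"]),
            set(payload["elevated_dlb"]),
            {t: dict(d) for t, d in payload["trait_drivers"].items()},
            latent,
        )


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng((int(seed) + crc32(name.encode())) % 2**31)


def _resolve_driver(ref: str, panel, ad_only, dlb_only, shared):
    """Antigen id for a driver reference; None when the referenced planted
    set is too small (e.g. null configs), which drops the coupling."""
    if ref in panel:
        return ref
    try:
        kind, idx = ref.split(":")
        pool = {"elevated_ad": ad_only, "elevated_dlb": dlb_only, "elevated_shared": shared}[kind]
        idx = int(idx)
    except (ValueError, KeyError):
        raise SimConfigError(f"cannot resolve trait driver reference {ref!r}") from None
    return pool[idx] if idx < len(pool) else None


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Generate one synthetic cohort.

    Returns ``(fluorescence, subjects, truth)`` where ``fluorescence`` is the
    per-spot long table (subject_id, spot_id, spot_type, antigen_id,
    intensity), ``subjects`` holds diagnosis, sex, age and the configured
    traits, and ``truth`` is the :class:`TruthLedger`.  Identical
    config + seed reproduces byte-identical outputs.
    """
    config.validate()
    width = max(5, len(str(config.n_antigens)))
    panel = [f"AG{i + 1:0{width}d}" for i in range(config.n_antigens)]

    rng_panel = _substream(config.seed, "panel")
    n_planted = config.n_elev_ad_only + config.n_elev_dlb_only + config.n_elev_shared
    chosen = list(rng_panel.choice(config.n_antigens, size=n_planted, replace=False)) if n_planted else []
    shared = [panel[i] for i in chosen[: config.n_elev_shared]]
    ad_only = [panel[i] for i in chosen[config.n_elev_shared : config.n_elev_shared + config.n_elev_ad_only]]
    dlb_only = [panel[i] for i in chosen[config.n_elev_shared + config.n_elev_ad_only :]]
    elevated_ad = set(shared) | set(ad_only)
    elevated_dlb = set(shared) | set(dlb_only)

    groups = (["AD"] * config.n_ad) + (["DLB"] * config.n_dlb) + (["CNI"] * config.n_cni)
    n_subj = len(groups)
    subj_ids = [f"S{i + 1:03d}" for i in range(n_subj)]

    rng_subj = _substream(config.seed, "subjects")
    female_frac = {"AD": config.female_frac_ad, "DLB": config.female_frac_dlb, "CNI": config.female_frac_cni}
    sex = ["F" if rng_subj.random() < female_frac[g] else "M" for g in groups]
    age = rng_subj.uniform(*config.age_range, size=n_subj).round(1)

    rng_lat = _substream(config.seed, "latent")
    latent = rng_lat.lognormal(config.background_log_mean, config.background_log_sd,
                               size=(n_subj, config.n_antigens))
    latent = pd.DataFrame(latent, index=subj_ids, columns=panel)
    grp = np.asarray(groups)
    if elevated_ad:
        latent.loc[grp == "AD", sorted(elevated_ad)] *= config.effect_fold
    if elevated_dlb:
        latent.loc[grp == "DLB", sorted(elevated_dlb)] *= config.effect_fold

    # traits: group baseline + coef * standardized driver latent AU + noise
    rng_tr = _substream(config.seed, "traits")
    trait_cols = {}
    trait_drivers: dict = {}
    for trait, spec in config.trait_model.items():
        mean = np.array([spec.baselines[g][0] for g in groups])
        sd = np.array([spec.baselines[g][1] for g in groups])
        value = mean + rng_tr.normal(0.0, 1.0, size=n_subj) * sd
        resolved = {}
        for ref, coef in spec.drivers.items():
            ag = _resolve_driver(ref, set(panel), ad_only, dlb_only, shared)
            if ag is None:
                continue
            col = latent[ag].to_numpy()
            z = (col - col.mean()) / (col.std() or 1.0)
            value = value + coef * z
            resolved[ag] = coef
        if resolved:
            trait_drivers[trait] = resolved
        if spec.binary:
            value = (value > 0.5).astype(int)
        else:
            if spec.bounds is not None:
                value = np.clip(value, *spec.bounds)
            value = np.round(value).astype(int) if spec.integer else np.round(value, 2)
        trait_cols[trait] = value

    subjects = pd.DataFrame(
        {"subject_id": subj_ids, "diagnosis": groups, "sex": sex, "age": age, **trait_cols}
    )

    # fluorescence: back-compute spot intensity from latent AU, then jitter
    rng_noise = _substream(config.seed, "intensity")
    sigma = np.sqrt(np.log1p(config.measurement_cv**2))
    f_pos, f_neg = config.pos_control_level, config.neg_control_level
    records = []
    for si, sid in enumerate(subj_ids):
        clean = f_neg + latent.iloc[si].to_numpy() / 100.0 * (f_pos - f_neg)
        noise = rng_noise.lognormal(-sigma**2 / 2.0, sigma, size=config.n_antigens) if sigma > 0 else 1.0
        intens = clean * noise
        for ai, ag in enumerate(panel):
            records.append((sid, f"{sid}_ag{ai + 1:05d}", "antigen", ag, intens[ai]))
        for kind, level, count in (("pos_control", f_pos, config.n_pos_controls),
                                   ("neg_control", f_neg, config.n_neg_controls)):
            jitter = rng_noise.lognormal(-sigma**2 / 2.0, sigma, size=count) if sigma > 0 else np.ones(count)
            for ci in range(count):
                records.append((sid, f"{sid}_{kind[:3]}{ci + 1:02d}", kind, "", level * jitter[ci]))
    fluorescence = pd.DataFrame(
        records, columns=["subject_id", "spot_id", "spot_type", "antigen_id", "intensity"]
    )
    fluorescence["intensity"] = fluorescence["intensity"].round(4)

    truth = TruthLedger(elevated_ad, elevated_dlb, trait_drivers, latent)
    return fluorescence, subjects, truth


def generate_sequences(panel, length_range=(50, 200), seed: int = 0, duplicate_pairs=None):
    """Random amino-acid sequences, one per antigen id.

    ``duplicate_pairs`` is an optional list of ``(id_a, id_b, identity)``
    tuples: ``id_b``'s sequence is rewritten as a copy of ``id_a``'s mutated
    to approximately the requested fractional identity (1.0 gives an exact
    copy), for alignment tests.  Returns Biopython ``SeqRecord`` objects.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    panel = list(panel)
    if not panel:
        raise ValueError("antigen panel is empty")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    seqs = {}
    for ag in panel:
        n = int(rng.integers(lo, hi + 1))
        seqs[ag] = "".join(rng.choice(letters, size=n))
    for (a, b, identity) in duplicate_pairs or []:
        if not (0.0 <= identity <= 1.0):
            raise ValueError(f"identity must be in [0, 1], got {identity}")
        base = list(seqs[a])
        n_mut = round((1.0 - identity) * len(base))
        pos = rng.choice(len(base), size=n_mut, replace=False)
        for p in pos:
            alt = [c for c in AMINO_ACIDS if c != base[p]]
            base[p] = alt[int(rng.integers(len(alt)))]
        seqs[b] = "".join(base)
    return [SeqRecord(Seq(s), id=ag, description="synthetic antigen") for ag, s in seqs.items()]


def write_fluorescence_tsv(fluorescence: pd.DataFrame, path) -> None:
    fluorescence.to_csv(path, sep="\t", index=False)


def read_fluorescence_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"antigen_id": str}, keep_default_na=False)
    df["intensity"] = df["intensity"].astype(float)
    return df
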