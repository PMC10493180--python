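"""Synthetic dataset bundles with planted latent-group structure.

Drugs belong to latent groups; in designated "signal" modalities each group
has a characteristic subset of feature columns that its members switch on
with high probability, so within-group Jaccard similarity exceeds
between-group similarity. The event label of a drug pair is a function of
the two drugs' groups (optionally noised), which makes similarity-based
pair classification learnable by construction — and makes ablation oracles
possible, because the ground-truth record says which modalities carried
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import DatasetBundle, FeatureMatrix, PairDataset

__all__ = ["SynthConfig", "GroundTruth", "generate", "make_ds_shaped", "DS_SHAPES"]

# drug count, modality names, per-modality feature counts, pair count, event count
DS_SHAPES = {
    "DS1": {
        "m": 572,
        "modalities": ["side_effect", "target", "enzyme", "substructure", "pathway"],
        "feature_counts": [9991, 1162, 202, 881, 957],
        "n_pairs": 37264,
        "n_events": 65,
    },
    "DS2": {
        "m": 1258,
        "modalities": ["target", "enzyme", "substructure"],
        "feature_counts": [1651, 316, 2040],
        "n_pairs": 161770,
        "n_events": 100,
    },
    "DS3": {
        "m": 645,
        "modalities": ["side_effect", "target"],
        "feature_counts": [10184, 8934],
        "n_pairs": 63473,
        "n_events": 185,
    },
}


@dataclass
class SynthConfig:
    m: int = 120
    modality_names: list[str] = field(default_factory=lambda: ["modA", "modB"])
    feature_counts: list[int] = field(default_factory=lambda: [200, 200])
    n_groups: int = 4
    within_group_on_prob: float = 0.9
    between_noise_prob: float = 0.02
    n_events: int = 6
    n_pairs: int = 1000
    label_noise: float = 0.0
    event_imbalance: float = 1.0  # power-law exponent over events; 0 = uniform
    signal_modalities: list[str] | None = None  # default: all modalities
    profile_fraction: float = 0.15  # share of a modality's columns in each group profile
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.modality_names) != len(self.feature_counts):
            raise ValueError("modality_names and feature_counts must align")
        if not self.modality_names:
            raise ValueError("need at least one modality")
        max_events = self.n_groups * (self.n_groups + 1) // 2
        if self.n_events > max_events:
            raise ValueError(
                f"n_events={self.n_events} exceeds the {max_events} unordered "
                f"group pairs of {self.n_groups} groups"
            )
        for prob in (self.within_group_on_prob, self.between_noise_prob):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must lie in [0, 1)")
        if self.signal_modalities is not None:
            unknown = set(self.signal_modalities) - set(self.modality_names)
            if unknown:
                raise ValueError(f"unknown signal modalities: {sorted(unknown)}")

    @property
    def p(self) -> int:
        return len(self.modality_names)

    def signal_set(self) -> set[str]:
        return set(
            self.modality_names if self.signal_modalities is None else self.signal_modalities
        )


@dataclass
class GroundTruth:
    """What the generator planted: group memberships and the label rule."""

    groups: np.ndarray  # group index per drug
    group_pair_event: dict[tuple[int, int], int]  # unordered group pair -> event
    signal_modalities: list[str]
    group_profiles: dict[str, list[np.ndarray]]  # modality -> per-group column sets
    clean_labels: np.ndarray  # pre-noise event per record


def _weighted_sample_without_replacement(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Gumbel top-k: O(n) weighted sampling without replacement."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=len(weights))
    return np.argpartition(-keys, size - 1)[:size] if size < len(weights) else np.arange(len(weights))


def generate(config: SynthConfig) -> tuple[DatasetBundle, GroundTruth]:
    """Draw a full bundle plus its ground-truth record from one seed."""
    rng = np.random.default_rng(config.seed)
    m, g = config.m, config.n_groups
    groups = rng.integers(0, g, size=m)

    # every unordered group pair gets an event; the first n_events pairs (in
    # shuffled order) pin down one pair per event so all events are reachable
    group_pairs = [(a, b) for a in range(g) for b in range(a, g)]
    order = rng.permutation(len(group_pairs))
    weights = (1.0 + np.arange(config.n_events)) ** -config.event_imbalance
    weights /= weights.sum()
    pair_event: dict[tuple[int, int], int] = {}
    for rank, idx in enumerate(order):
        if rank < config.n_events:
            pair_event[group_pairs[idx]] = rank
        else:
            pair_event[group_pairs[idx]] = int(rng.choice(config.n_events, p=weights))

    signal = config.signal_set()
    mats: list[FeatureMatrix] = []
    profiles: dict[str, list[np.ndarray]] = {}
    drug_ids = [f"D{k:04d}" for k in range(m)]
    for name, c in zip(config.modality_names, config.feature_counts):
        values = (rng.random((m, c)) < config.between_noise_prob).astype(np.int8)
        if name in signal:
            profile_size = max(1, round(config.profile_fraction * c))
            mod_profiles = [
                np.sort(rng.choice(c, size=profile_size, replace=False)) for _ in range(g)
            ]
            profiles[name] = mod_profiles
            for grp in range(g):
                members = np.flatnonzero(groups == grp)
                cols = mod_profiles[grp]
                on = rng.random((len(members), len(cols))) < config.within_group_on_prob
                values[np.ix_(members, cols)] = np.maximum(
                    values[np.ix_(members, cols)], on.astype(np.int8)
                )
        columns = [f"{name}_f{k}" for k in range(c)]
        mats.append(FeatureMatrix(name, list(drug_ids), columns, values))

    # candidate drug pairs, weighted by their event's target frequency
    max_pairs = m * (m - 1) // 2
    if config.n_pairs > max_pairs:
        raise ValueError(f"n_pairs={config.n_pairs} exceeds the {max_pairs} distinct pairs")
    iu, ju = np.triu_indices(m, k=1)
    cand_events = np.array(
        [pair_event[(min(a, b), max(a, b))] for a, b in zip(groups[iu], groups[ju])]
    )
    pair_weights = weights[cand_events]
    chosen = _weighted_sample_without_replacement(pair_weights, config.n_pairs, rng)
    chosen = np.sort(chosen)

    clean = cand_events[chosen]
    labels = clean.copy()
    if config.label_noise > 0:
        flip = rng.random(len(labels)) < config.label_noise
        for r in np.flatnonzero(flip):
            alt = rng.integers(0, config.n_events - 1)
            labels[r] = alt if alt < labels[r] else alt + 1

    # keep only events that actually occur; remap to contiguous indices in
    # first-appearance order so the pair dataset invariants hold
    remap: dict[int, int] = {}
    records = []
    for r, idx in enumerate(chosen):
        e = int(labels[r])
        if e not in remap:
            remap[e] = len(remap)
        records.append((int(iu[idx]), int(ju[idx]), remap[e]))
    event_labels = [f"E{e:03d}" for e in remap]
    pairs = PairDataset(list(drug_ids), records, event_labels)
    truth = GroundTruth(
        groups=groups,
        group_pair_event={gp: remap.get(e, -1) for gp, e in pair_event.items()},
        signal_modalities=sorted(signal),
        group_profiles=profiles,
        clean_labels=np.array([remap.get(int(e), -1) for e in clean]),
    )
    return DatasetBundle(mats, pairs), truth


def make_ds_shaped(dataset: str, scale: float = 1.0, **overrides) -> SynthConfig:
    """A config whose shape counts mirror one of the published benchmarks,
    multiplied by ``scale`` (rounded, minimums enforced)."""
    if dataset not in DS_SHAPES:
        raise ValueError(f"unknown dataset {dataset!r}; choose from {sorted(DS_SHAPES)}")
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    shape = DS_SHAPES[dataset]
    m = max(10, round(shape["m"] * scale))
    n_events = max(2, round(shape["n_events"] * scale))
    feature_counts = [max(8, round(c * scale)) for c in shape["feature_counts"]]
    # pair count shrinks with the square of scale (pair space is quadratic in m)
    n_pairs = min(
        max(20 * n_events, round(shape["n_pairs"] * scale * scale)),
        m * (m - 1) // 2,
    )
    n_groups = 2
    while n_groups * (n_groups + 1) // 2 < n_events:
        n_groups += 1
    defaults = dict(
        m=m,
        modality_names=list(shape["modalities"]),
        feature_counts=feature_counts,
        n_groups=n_groups,
        n_events=n_events,
        n_pairs=n_pairs,
        event_imbalance=1.0,
        within_group_on_prob=0.9,
        between_noise_prob=0.02,
        seed=0,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)
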