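"""Synthetic drug networks and oncogene expression profiles with known truth.

The generator emulates, at toy scale, the structure the pipeline is built
for: a compendium of drug prototype ranked lists partitioned into
mode-of-action communities of correlated profiles, plus paired
wild-type/mutant expression vectors whose differential carries planted up-
and down-regulated gene sets.  One community of "inhibitor" drugs is planted
whose prototype is the *reverse* of the oncogene signature, so that querying
the network with the reversed oncogene signature should recover exactly
those drugs — ground truth for every downstream stage.

Noise model
-----------
Drug PRLs are noisy copies of their community prototype: Gaussian jitter of
standard deviation ``noise_sd * n_genes`` is added to the prototype's rank
positions and the features are re-ranked.  ``noise_sd`` is therefore a
dimensionless fraction of the list length; 0 gives exact copies and values
around 0.3 give strongly correlated but clearly distinct profiles.
Expression-score noise in the oncogene profiles uses ``noise_sd`` directly
in score units against a planted effect of ``signal_strength``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sigrev.ranking import RankedList, rank_from_scores, reverse_signature

INHIBITOR_COMMUNITY = "inhibitors"

# RNG stream tags: every consumer draws from an independent, reproducible
# stream keyed by (seed, tag[, index]).
_STREAM_ONCOGENE = 0
_STREAM_REPLICATE = 1
_STREAM_PROTOTYPE = 2
_STREAM_DRUG = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults are the calibration configuration used throughout the test
    suite: 1000 genes, 60 drugs in 6 communities of which one holds the 5
    planted inhibitors, 50 planted up- and 50 down-regulated genes, and
    noise_sd 0.3.
    """

    n_genes: int = 1000
    n_drugs: int = 60
    n_communities: int = 6
    n_inhibitors: int = 5
    n_signal_genes: int = 50
    noise_sd: float = 0.3
    seed: int = 0
    signal_strength: float = 3.0

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise ValueError("n_genes must be >= 4")
        if not (1 <= self.n_inhibitors <= self.n_drugs):
            raise ValueError("need 1 <= n_inhibitors <= n_drugs")
        if 2 * self.n_signal_genes > self.n_genes:
            raise ValueError("2*n_signal_genes must not exceed n_genes")
        if not (1 <= self.n_communities <= self.n_drugs):
            raise ValueError("need 1 <= n_communities <= n_drugs")
        if self.n_drugs - self.n_inhibitors < self.n_communities - 1:
            raise ValueError("too few non-inhibitor drugs for the community count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class OncogeneTruth:
    """Planted differential-expression gene sets of the mutant profile."""

    up: frozenset[str]
    down: frozenset[str]


@dataclass(frozen=True)
class DrugNetworkTruth:
    """Planted structure of the synthetic compendium."""

    inhibitors: frozenset[str]
    communities: dict[str, str] = field(hash=False)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, tags)])


def gen_oncogene_profile(
    cfg: SyntheticConfig, replicate: int = 0
) -> tuple[dict[str, float], dict[str, float], OncogeneTruth]:
    """Paired wild-type/mutant expression vectors with planted signal.

    Returns ``(wt_scores, mut_scores, truth)``.  The differential
    ``mut - wt`` places the planted up-set near ``+signal_strength``, the
    down-set near ``-signal_strength``, and background genes at zero-mean
    Gaussian noise of scale ``noise_sd``.

    The planted gene sets and the wild-type baseline depend only on
    ``cfg.seed``; the mutant measurement noise additionally depends on
    ``replicate``, so distinct replicates are independent noisy readouts of
    the same biological truth — the raw material for replicate query nodes.
    """
    genes = _gene_ids(cfg.n_genes)
    base_rng = _rng(cfg.seed, _STREAM_ONCOGENE)
    planted = base_rng.choice(cfg.n_genes, size=2 * cfg.n_signal_genes, replace=False)
    up_idx = planted[: cfg.n_signal_genes]
    down_idx = planted[cfg.n_signal_genes:]
    wt = base_rng.normal(loc=7.0, scale=1.0, size=cfg.n_genes)

    delta = np.zeros(cfg.n_genes)
    delta[up_idx] = cfg.signal_strength
    delta[down_idx] = -cfg.signal_strength
    noise_rng = _rng(cfg.seed, _STREAM_REPLICATE, replicate)
    noise = noise_rng.normal(scale=cfg.noise_sd, size=cfg.n_genes) if cfg.noise_sd > 0 else 0.0
    mut = wt + delta + noise

    wt_scores = {g: float(v) for g, v in zip(genes, wt)}
    mut_scores = {g: float(v) for g, v in zip(genes, mut)}
    truth = OncogeneTruth(
        up=frozenset(genes[i] for i in up_idx),
        down=frozenset(genes[i] for i in down_idx),
    )
    return wt_scores, mut_scores, truth


def differential_scores(
    wt_scores: dict[str, float], mut_scores: dict[str, float]
) -> dict[str, float]:
    """Mutant-minus-wild-type differential score per gene."""
    if set(wt_scores) != set(mut_scores):
        raise ValueError("wt and mut score vectors cover different genes")
    return {g: mut_scores[g] - wt_scores[g] for g in wt_scores}


def _jitter_ranking(
    prototype: RankedList, noise_sd: float, rng: np.random.Generator, node_id: str
) -> RankedList:
    """Noisy copy of a prototype: jitter rank positions, re-rank."""
    n = prototype.n
    positions = np.arange(1, n + 1, dtype=float)
    if noise_sd > 0:
        positions = positions + rng.normal(scale=noise_sd * n, size=n)
    # smaller jittered position = nearer the top; lexicographic tie-break
    order = sorted(zip(positions, prototype.features))
    return RankedList(node_id=node_id, features=tuple(f for _, f in order))


def gen_drug_network(
    cfg: SyntheticConfig, oncogene_signature: RankedList
) -> tuple[dict[str, RankedList], dict[str, str], DrugNetworkTruth]:
    """Drug PRL compendium with planted inhibitor community.

    Each community has a latent prototype ranking; member drugs are noisy
    rank-jittered copies of it.  The inhibitor community's prototype is the
    reverse of ``oncogene_signature``, so its members anti-correlate with the
    oncogenic profile.  Returns ``(prls, community_labels, truth)``.
    """
    if oncogene_signature.n != cfg.n_genes:
        raise ValueError(
            f"signature universe size {oncogene_signature.n} != n_genes {cfg.n_genes}"
        )
    genes = list(oncogene_signature.features)

    prototypes: list[RankedList] = [
        reverse_signature(
            RankedList(node_id="oncogene", features=tuple(genes))
        ).with_node_id(f"{INHIBITOR_COMMUNITY}-prototype")
    ]
    for c in range(1, cfg.n_communities):
        proto_rng = _rng(cfg.seed, _STREAM_PROTOTYPE, c)
        perm = proto_rng.permutation(cfg.n_genes)
        prototypes.append(
            RankedList(
                node_id=f"community_{c}-prototype",
                features=tuple(genes[i] for i in perm),
            )
        )

    # community sizes: inhibitors fixed, remainder split as evenly as possible
    sizes = [cfg.n_inhibitors]
    rest = cfg.n_drugs - cfg.n_inhibitors
    others = cfg.n_communities - 1
    for c in range(others):
        sizes.append(rest // others + (1 if c < rest % others else 0))

    prls: dict[str, RankedList] = {}
    labels: dict[str, str] = {}
    drug_index = 0
    name_width = len(str(cfg.n_drugs))
    for c, (proto, size) in enumerate(zip(prototypes, sizes)):
        community = INHIBITOR_COMMUNITY if c == 0 else f"community_{c}"
        for _ in range(size):
            if c == 0:
                name = f"inhibitor_{drug_index:0{name_width}d}"
            else:
                name = f"drug_{drug_index:0{name_width}d}"
            drug_rng = _rng(cfg.seed, _STREAM_DRUG, drug_index)
            prls[name] = _jitter_ranking(proto, cfg.noise_sd, drug_rng, name)
            labels[name] = community
            drug_index += 1

    truth = DrugNetworkTruth(
        inhibitors=frozenset(d for d, c in labels.items() if c == INHIBITOR_COMMUNITY),
        communities=dict(labels),
    )
    return prls, labels, truth
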