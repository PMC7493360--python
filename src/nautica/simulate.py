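"""Seeded synthetic fixtures: PPI networks, planted TF pairs, complex DBs.

The generator emulates the statistical structure the classifier assumes:
a scale-free (preferential-attachment) PPI backbone, co-operating TF pairs
that share many partners and usually have a direct edge, competing pairs
that share few partners and rarely a direct edge, non-interacting pairs that
share almost none, and a noisy boolean positional-prediction label per pair.
Every quantity is drawn from a :class:`numpy.random.Generator` seeded from
the configuration, so runs are bit-reproducible.

Planted pairs use disjoint TF sets, which makes planting non-interfering:
adding a shared partner k to pair (a, b) only changes the neighbourhoods of
a, b and k, none of which can alter the common-neighbour count of a pair
that contains neither a nor b. The truth record nevertheless stores features
recomputed from the final graph, never the requested targets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .candidates import CandidatePair
from .classify import InteractionLabel
from .enrichment import ComplexDB
from .errors import ConfigError
from .network import PPINetwork, PairFeatures, bin_index, pair_features, shared_interactors

logger = logging.getLogger(__name__)

_CLASS_ORDER = [InteractionLabel.NINT, InteractionLabel.COMP, InteractionLabel.COOP]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    ``class_mix`` is (NINT, COMP, COOP) fractions of planted curated pairs,
    defaulting to the composition of a literature-curated training set in
    this problem (non-interactions and competitions are rare in curation
    because they are hard to document; co-operations dominate). Shared-
    partner counts are Poisson around per-class means chosen so that
    co-operations sit well above the fitted thresholds (tau_L=5, tau_H=8)
    and competitions/non-interactions below. ``tica_tpr``/``tica_fpr`` are
    the sensitivity/false-positive rate of the upstream positional predictor
    (an interaction — COOP or COMP — is flagged with probability tpr, a
    non-interaction with probability fpr).
    """

    seed: int = 0
    n_proteins: int = 2000
    n_tfs: int = 120
    attachment_edges: int = 4
    n_pairs: int = 45
    class_mix: tuple[float, float, float] = (0.20, 0.15, 0.65)  # NINT, COMP, COOP
    nint_shared_mean: float = 0.5
    comp_shared_mean: float = 1.0
    coop_shared_mean: float = 12.0
    coop_edge_prob: float = 0.8
    comp_edge_prob: float = 0.05
    tica_tpr: float = 0.9
    tica_fpr: float = 0.05
    contexts: tuple[str, ...] = ("HEPG2", "GM12878", "K562")

    def __post_init__(self):
        if not 1 <= self.attachment_edges < self.n_proteins:
            raise ConfigError("need 1 <= attachment_edges < n_proteins")
        if self.n_tfs > self.n_proteins:
            raise ConfigError("n_tfs cannot exceed n_proteins")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise ConfigError("class_mix must be non-negative and sum to 1")
        for p in (self.coop_edge_prob, self.comp_edge_prob,
                  self.tica_tpr, self.tica_fpr):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        for m in (self.nint_shared_mean, self.comp_shared_mean,
                  self.coop_shared_mean):
            if m < 0:
                raise ConfigError("shared-partner means must be non-negative")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([cfg.seed, stream])


def generate_network(cfg: SimulationConfig) -> tuple[PPINetwork, list[str]]:
    """Preferential-attachment PPI backbone plus a random TF subset.

    The Barabasi-Albert process yields the heavy-tailed degree distribution
    typical of PPI networks. Node symbols are P00000.. and TF status is
    assigned to a uniform random subset of nodes.
    """
    rng = _rng(cfg, 0)
    ba = nx.barabasi_albert_graph(
        cfg.n_proteins, cfg.attachment_edges,
        seed=int(rng.integers(2**31)),
    )
    mapping = {i: f"P{i:05d}" for i in ba.nodes}
    g = nx.relabel_nodes(ba, mapping)
    nx.set_edge_attributes(g, frozenset({"physical"}), "tags")
    tf_nodes = sorted(
        mapping[i] for i in rng.choice(cfg.n_proteins, cfg.n_tfs, replace=False)
    )
    net = PPINetwork(graph=g, tf_flags={t: True for t in tf_nodes})
    return net, tf_nodes


def _plant_shared_partners(
    net: PPINetwork, a: str, b: str, target: int, rng: np.random.Generator
) -> None:
    """Add edges so that a and b share at least ``target`` partners."""
    g = net.graph
    current = (set(g[a]) & set(g[b])) - {a, b}
    deficit = target - len(current)
    if deficit <= 0:
        return
    pool = sorted(set(g.nodes) - current - {a, b})
    if deficit > len(pool):
        raise ConfigError(
            f"cannot plant {target} shared partners for {a}/{b}: network too small"
        )
    for k in rng.choice(len(pool), deficit, replace=False):
        node = pool[k]
        g.add_edge(a, node, tags=frozenset({"planted"}))
        g.add_edge(b, node, tags=frozenset({"planted"}))


def plant_pairs(
    cfg: SimulationConfig, net: PPINetwork
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant labelled TF pairs into the network (mutating it).

    Returns (curated, predictions, truth) tables. The curated table mirrors
    a literature-curated label file; the prediction table carries per-context
    noisy boolean labels; the truth record stores the exact planted class and
    the features recomputed from the final graph.
    """
    rng = _rng(cfg, 1)
    eligible = sorted(
        t for t, f in net.tf_flags.items()
        if f and net.graph.degree[t] >= 3
    )
    if 2 * cfg.n_pairs > len(eligible):
        raise ConfigError(
            f"need {2 * cfg.n_pairs} eligible TFs for {cfg.n_pairs} disjoint "
            f"pairs, have {len(eligible)}"
        )
    chosen = rng.choice(len(eligible), 2 * cfg.n_pairs, replace=False)
    pairs = [
        tuple(sorted((eligible[chosen[2 * i]], eligible[chosen[2 * i + 1]])))
        for i in range(cfg.n_pairs)
    ]
    labels = rng.choice(len(_CLASS_ORDER), cfg.n_pairs, p=list(cfg.class_mix))

    means = {
        InteractionLabel.NINT: cfg.nint_shared_mean,
        InteractionLabel.COMP: cfg.comp_shared_mean,
        InteractionLabel.COOP: cfg.coop_shared_mean,
    }
    edge_probs = {
        InteractionLabel.NINT: 0.0,
        InteractionLabel.COMP: cfg.comp_edge_prob,
        InteractionLabel.COOP: cfg.coop_edge_prob,
    }

    curated_rows, pred_rows, truth_rows = [], [], []
    for (a, b), li in zip(pairs, labels):
        label = _CLASS_ORDER[li]
        target = int(rng.poisson(means[label]))
        _plant_shared_partners(net, a, b, target, rng)
        want_edge = rng.random() < edge_probs[label]
        if want_edge:
            if not net.graph.has_edge(a, b):
                net.graph.add_edge(a, b, tags=frozenset({"planted"}))
        elif net.graph.has_edge(a, b):
            net.graph.remove_edge(a, b)

        feats = pair_features(net, a, b)
        is_interaction = label is not InteractionLabel.NINT
        flag_prob = cfg.tica_tpr if is_interaction else cfg.tica_fpr
        tica = bool(rng.random() < flag_prob)
        if tica:
            n_support = int(rng.integers(1, len(cfg.contexts) + 1))
            support = set(
                cfg.contexts[j]
                for j in rng.choice(len(cfg.contexts), n_support, replace=False)
            )
        else:
            support = set()
        for ctx in cfg.contexts:
            pred_rows.append(
                {"tf_a": a, "tf_b": b, "context": ctx,
                 "predicted": int(ctx in support)}
            )
        curated_rows.append(
            {"tf_a": a, "tf_b": b, "label": label.value, "source": "planted"}
        )
        truth_rows.append({
            "tf_a": a, "tf_b": b, "label": label.value,
            "direct_edge": feats.direct_edge, "n12": feats.n12,
            "bin": feats.bin, "tica_label": tica,
        })
    return (
        pd.DataFrame(curated_rows),
        pd.DataFrame(pred_rows),
        pd.DataFrame(truth_rows),
    )


def generate_complexes(
    truth: pd.DataFrame,
    coverage: float = 0.3,
    leak: float = 0.02,
    seed: int = 0,
) -> ComplexDB:
    """Place planted pairs into synthetic complexes.

    A fraction ``coverage`` of COOP pairs is put into a complex of its own
    (curated complex databases are incomplete, so coverage well below 1 is
    realistic); COMP and NINT pairs co-occur only at the small ``leak`` rate.
    By construction class enrichment then shows COOP >> COMP ~ NINT.
    """
    if not 0.0 <= coverage <= 1.0 or not 0.0 <= leak <= 1.0:
        raise ConfigError("coverage and leak must lie in [0, 1]")
    rng = np.random.default_rng([seed, 2])
    complexes: dict[str, frozenset[str]] = {}
    for i, row in truth.iterrows():
        p = coverage if row["label"] == InteractionLabel.COOP.value else leak
        if rng.random() < p:
            complexes[f"CPX{i:04d}"] = frozenset({row["tf_a"], row["tf_b"]})
    return ComplexDB(complexes)


def plant_separable_training(
    tau_l: int,
    tau_h: int,
    n_random: int = 6,
    n12_max: int = 20,
    seed: int = 0,
) -> list[tuple[CandidatePair, InteractionLabel]]:
    """A perfectly separable training set whose recall optimum is exactly
    (tau_l, tau_h).

    For every branch of the decision tree, pairs are planted on both sides
    of the branch's threshold, including the two boundary values, so that
    all three class recalls equal 1 at the planted thresholds and at least
    one boundary pair is misclassified anywhere else on the grid.
    """
    if tau_l < 1 or tau_h < 1:
        raise ConfigError("planted thresholds must be >= 1")
    if n12_max <= max(tau_l, tau_h):
        raise ConfigError("n12_max must exceed both thresholds")
    rng = np.random.default_rng([seed, 3])
    counter = 0

    def make(tica: bool, edge: bool, n12: int, label: InteractionLabel):
        nonlocal counter
        a, b = f"TA{counter:04d}", f"TB{counter:04d}"
        counter += 1
        feats = PairFeatures(a, b, edge, n12, bin_index(n12))
        return (CandidatePair(feats, tica, []), label)

    def spread(lo: int, hi: int, mandatory: list[int]) -> list[int]:
        extra = rng.integers(lo, hi + 1, size=n_random).tolist() if hi >= lo else []
        return mandatory + extra

    COOP, COMP, NINT = (
        InteractionLabel.COOP, InteractionLabel.COMP, InteractionLabel.NINT
    )
    train = []
    # branch (tica, edge): COOP regardless of N12
    for n in spread(0, n12_max, [0, n12_max]):
        train.append(make(True, True, int(n), COOP))
    # branch (tica, no edge): COMP below tau_l, COOP at and above
    for n in spread(0, tau_l - 1, [tau_l - 1]):
        train.append(make(True, False, int(n), COMP))
    for n in spread(tau_l, n12_max, [tau_l]):
        train.append(make(True, False, int(n), COOP))
    # branch (no tica, edge): NINT below tau_l, COOP at and above
    for n in spread(0, tau_l - 1, [tau_l - 1]):
        train.append(make(False, True, int(n), NINT))
    for n in spread(tau_l, n12_max, [tau_l]):
        train.append(make(False, True, int(n), COOP))
    # branch (no tica, no edge): NINT below tau_h, COMP at and above
    for n in spread(0, tau_h - 1, [tau_h - 1]):
        train.append(make(False, False, int(n), NINT))
    for n in spread(tau_h, n12_max, [tau_h]):
        train.append(make(False, False, int(n), COMP))
    return train


def write_fixtures(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full fixture set and write it in the formats the readers
    expect. Returns a name -> path manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, tf_list = generate_network(cfg)
    curated, predictions, truth = plant_pairs(cfg, net)
    complexes = generate_complexes(truth, seed=cfg.seed)

    paths = {
        "network": out_dir / "network.tsv",
        "tf_list": out_dir / "tfs.txt",
        "predictions": out_dir / "predictions.tsv",
        "curated": out_dir / "curated.tsv",
        "complexes": out_dir / "complexes.tsv",
        "truth": out_dir / "truth.tsv",
    }
    with open(paths["network"], "w") as fh:
        for a, b in sorted(net.edges):
            tags = ",".join(sorted(net.graph.edges[a, b].get("tags", ())))
            fh.write(f"{a}\t{b}\t{tags}\n")
    with open(paths["tf_list"], "w") as fh:
        fh.write("# synthetic TF list\n")
        for t in tf_list:
            fh.write(t + "\n")
    predictions.to_csv(paths["predictions"], sep="\t", index=False)
    curated.to_csv(paths["curated"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["complexes"], "w") as fh:
        fh.write("ComplexID\tsubunits(Gene name)\n")
        for cid, members in sorted(complexes.complexes.items()):
            fh.write(f"{cid}\t{';'.join(sorted(members))}\n")
    return paths
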