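"""Recurrent dense network for run/turn state classification.

Architecture: nine densely connected linear layers alternating with ReLU
activations, plus a bidirectional LSTM layer at the beginning and at the
middle of the sequence — eleven layers in all — ending in a softmax over
the behavioral states.  Training weights the cross-entropy loss 10-fold
toward turn frames (turns are rare against a background of forward
crawling); at inference the per-frame probabilities are decoded through
the switching-penalty dynamic program shared with the heuristic classifier
(:func:`larvatrack.behavior.viterbi_smooth`), which adds an explicit cost
for changing behavioral state between frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..behavior import viterbi_smooth
from .autograd import Adam, Tensor
from .layers import BiLSTM, Linear, Module, cross_entropy, softmax

__all__ = ["StateNetConfig", "StateClassifierNet", "train_state_network"]


@dataclass(frozen=True)
class StateNetConfig:
    n_features: int = 4        # per-frame inputs (bend, speed, bend rate, ...)
    hidden: int = 16
    n_states: int = 2          # run, turn
    turn_weight: float = 10.0  # loss weighting on turn frames
    rng_seed: int = 0


class StateClassifierNet(Module):
    def __init__(self, cfg: StateNetConfig = StateNetConfig()):
        rng = np.random.default_rng(cfg.rng_seed)
        self.cfg = cfg
        h = cfg.hidden
        self.lstm_in = BiLSTM(cfg.n_features, h, rng)        # layer 1
        self.dense_a = [Linear(2 * h if i == 0 else h, h, rng)
                        for i in range(4)]                   # layers 2-5
        self.lstm_mid = BiLSTM(h, h, rng)                    # layer 6
        self.dense_b = [Linear(2 * h if i == 0 else h, h, rng)
                        for i in range(4)]                   # layers 7-10
        self.out = Linear(h, cfg.n_states, rng)              # layer 11

    def forward_sequence(self, features: np.ndarray) -> Tensor:
        """(T, n_features) -> (T, n_states) softmax probabilities."""
        f = np.asarray(features, dtype=float)
        xs = [Tensor(f[t:t + 1]) for t in range(len(f))]
        hs = self.lstm_in(xs)
        hs = [self._dense(self.dense_a, h) for h in hs]
        hs = self.lstm_mid(hs)
        hs = [self._dense(self.dense_b, h) for h in hs]
        from .autograd import concat
        stacked = concat([self.out(h) for h in hs], axis=0)
        return softmax(stacked, axis=-1)

    @staticmethod
    def _dense(layers, h: Tensor) -> Tensor:
        for lin in layers:
            h = lin(h).relu()
        return h

    def predict(self, features: np.ndarray, switch_cost: float = 2.0) -> np.ndarray:
        """Per-frame states after the switching-penalty dynamic program."""
        probs = self.forward_sequence(features).data
        return viterbi_smooth(probs, switch_cost)


def train_state_network(net: StateClassifierNet, sequences, labels,
                        epochs: int = 10, lr: float = 1e-2) -> list[float]:
    """Train on labelled sequences; loss is weighted toward turn frames.

    ``sequences``: iterable of (T_i, n_features) arrays; ``labels``:
    matching (T_i,) arrays of {0 run, 1 turn}.  Returns per-epoch losses.
    """
    opt = Adam(net.parameters(), lr=lr)
    losses = []
    for _ in range(epochs):
        total = 0.0
        for feats, lab in zip(sequences, labels):
            lab = np.asarray(lab, dtype=int)
            onehot = np.eye(net.cfg.n_states)[lab]
            weights = np.where(lab == 1, net.cfg.turn_weight, 1.0)
            opt.zero_grad()
            probs = net.forward_sequence(feats)
            loss = cross_entropy(probs, onehot, weights)
            loss.backward()
            opt.step()
            total += float(loss.data)
        losses.append(total / max(len(sequences), 1))
    return losses
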