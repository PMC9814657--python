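"""Character-level recurrent SMILES policy network (NumPy GRU).

The network is a single-layer GRU over learned token embeddings with a
linear projection to the vocabulary. It runs in two modes: teacher-forced
training (supervised pretraining, policy-gradient and replay losses all
reduce to weighted next-token negative log-likelihood) and autoregressive
sampling (multinomial at temperature 1.0, terminated by the STOP token or
truncated at ``max_length``).

Backpropagation through time is written out by hand; gradients are exact,
which the test suite verifies against central finite differences.
PAD and START are masked out of the output softmax: the policy can never
emit them, so the emission distribution is identical in both modes.
"""

from __future__ import annotations

import copy
import json
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .vocab import Trajectory, Vocabulary

__all__ = [
    "PolicyNetwork",
    "Adam",
    "pretrain_step",
    "sample_trajectories",
    "trajectory_logprobs",
    "weighted_nll_and_grads",
]

CHECKPOINT_VERSION = 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class PolicyNetwork:
    """GRU policy over a SMILES vocabulary.

    Parameters
    ----------
    vocab : Vocabulary
        Token<->id map; fixes the action space and ``max_length``.
    hidden_size : int
        GRU state width. 128 is ample for toy corpora.
    embed_dim : int
        Token embedding width.
    seed : int
        Initialization seed (scaled-normal init).
    """

    def __init__(
        self,
        vocab: Vocabulary,
        hidden_size: int = 128,
        embed_dim: int = 64,
        seed: int = 0,
    ) -> None:
        self.vocab = vocab
        self.hidden_size = hidden_size
        self.embed_dim = embed_dim
        self.max_length = vocab.max_length
        V, H, D = vocab.size, hidden_size, embed_dim
        rng = np.random.default_rng(seed)

        def init(*shape):
            fan_in = shape[0]
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

        # gate order along the 3H axis: update (z), reset (r), candidate (n)
        self.params: Dict[str, np.ndarray] = {
            "E": init(V, D),
            "W": init(D, 3 * H),
            "U": init(H, 3 * H),
            "b": np.zeros(3 * H),
            "Wo": init(H, V),
            "bo": np.zeros(V),
        }
        # ids the policy may never emit
        self._forbidden = np.array([vocab.pad_id, vocab.start_id])

    # ------------------------------------------------------------------
    # parameter plumbing
    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def set_flat(self, theta: np.ndarray) -> None:
        i = 0
        for k in sorted(self.params):
            p = self.params[k]
            p[...] = theta[i : i + p.size].reshape(p.shape)
            i += p.size
        if i != theta.size:
            raise ValueError("flat parameter vector has wrong length")

    def clone(self) -> "PolicyNetwork":
        other = copy.copy(self)
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    # ------------------------------------------------------------------
    # forward machinery
    # ------------------------------------------------------------------
    def _step(
        self, x_ids: np.ndarray, h: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray, tuple]:
        """One GRU step on a batch of token ids. Returns (probs, h_new, cache)."""
        P = self.params
        H = self.hidden_size
        x = P["E"][x_ids]  # (B, D)
        gx = x @ P["W"] + P["b"]  # (B, 3H)
        gh = h @ P["U"]  # (B, 3H)
        z = _sigmoid(gx[:, :H] + gh[:, :H])
        r = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
        hUn = gh[:, 2 * H :]
        n = np.tanh(gx[:, 2 * H :] + r * hUn)
        h_new = (1.0 - z) * n + z * h
        logits = h_new @ P["Wo"] + P["bo"]
        logits[:, self._forbidden] = -np.inf
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (x_ids, h, z, r, n, hUn, h_new, probs)
        return probs, h_new, cache

    def _forward(
        self, inputs: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray, List[tuple]]:
        """Teacher-forced forward pass over a padded (B, T) id batch.

        Returns per-step emission probabilities (B, T, V), final hidden
        states and the step caches for backprop.
        """
        B, T = inputs.shape
        h = np.zeros((B, self.hidden_size))
        probs = np.empty((B, T, self.vocab.size))
        caches: List[tuple] = []
        for t in range(T):
            p, h, cache = self._step(inputs[:, t], h)
            probs[:, t, :] = p
            caches.append(cache)
        return probs, h, caches

    def _backward(
        self,
        caches: List[tuple],
        targets: np.ndarray,
        weights: np.ndarray,
    ) -> Dict[str, np.ndarray]:
        """BPTT for the weighted NLL loss sum_{b,t} w[b,t] * nll[b,t]."""
        P = self.params
        H = self.hidden_size
        B, T = targets.shape
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        dh_next = np.zeros((B, H))
        rows = np.arange(B)
        for t in range(T - 1, -1, -1):
            x_ids, h_prev, z, r, n, hUn, h_new, probs = caches[t]
            # d loss / d logits for weighted cross-entropy
            dlogits = probs * weights[:, t][:, None]
            dlogits[rows, targets[:, t]] -= weights[:, t]
            grads["Wo"] += h_new.T @ dlogits
            grads["bo"] += dlogits.sum(axis=0)
            dh = dlogits @ P["Wo"].T + dh_next
            # GRU cell backward
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * hUn
            dhUn = dn_pre * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dgx = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
            dgh = np.concatenate([dz_pre, dr_pre, dhUn], axis=1)
            grads["W"] += P["E"][x_ids].T @ dgx
            grads["b"] += dgx.sum(axis=0)
            grads["U"] += h_prev.T @ dgh
            dh_prev += dgh @ P["U"].T
            dx = dgx @ P["W"].T
            np.add.at(grads["E"], x_ids, dx)
            dh_next = dh_prev
        return grads

    # ------------------------------------------------------------------
    # batching helpers
    # ------------------------------------------------------------------
    def pad_batch(
        self, batch: Sequence[Trajectory]
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Build START-prefixed inputs, targets and a validity mask.

        inputs[b] = [START, s_1, ..., s_{N-1}, PAD...]; targets[b] =
        [s_1, ..., s_N, PAD...]; mask is 1 on real target positions.
        """
        if not batch:
            raise ValueError("empty batch")
        T = max(len(t) for t in batch)
        B = len(batch)
        inputs = np.full((B, T), self.vocab.pad_id, dtype=np.int64)
        targets = np.full((B, T), self.vocab.pad_id, dtype=np.int64)
        mask = np.zeros((B, T))
        for b, traj in enumerate(batch):
            ids = list(traj.token_ids)
            if not ids:
                raise ValueError("empty trajectory")
            inputs[b, 0] = self.vocab.start_id
            inputs[b, 1 : len(ids)] = ids[:-1]
            targets[b, : len(ids)] = ids
            mask[b, : len(ids)] = 1.0
        return inputs, targets, mask

    def save(self, path: str) -> None:
        """Serialize parameters, vocabulary and dimensions to one .npz."""
        meta = json.dumps(
            {
                "version": CHECKPOINT_VERSION,
                "tokens": self.vocab.tokens,
                "max_length": self.vocab.max_length,
                "hidden_size": self.hidden_size,
                "embed_dim": self.embed_dim,
            }
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str) -> "PolicyNetwork":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        vocab = Vocabulary(tokens=meta["tokens"])
        vocab.max_length = meta["max_length"]
        model = cls(
            vocab,
            hidden_size=meta["hidden_size"],
            embed_dim=meta["embed_dim"],
        )
        for k in model.params:
            model.params[k] = data[k]
        return model


class Adam:
    """Adam optimizer over a PolicyNetwork's parameter dict."""

    def __init__(
        self,
        model: PolicyNetwork,
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.model.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------
def weighted_nll_and_grads(
    model: PolicyNetwork,
    batch: Sequence[Trajectory],
    weights: np.ndarray,
    compute_grads: bool = True,
) -> Tuple[float, Optional[Dict[str, np.ndarray]]]:
    """Loss = sum_{b,i} weights[b,i] * (-log p(s_i | s_{i-1}; theta)).

    Supervised pretraining, the policy-gradient loss and the replay loss
    are all instances of this with different weight matrices.
    """
    inputs, targets, mask = model.pad_batch(batch)
    w = weights * mask  # never score PAD positions
    probs, _, caches = model._forward(inputs)
    B, T = targets.shape
    p_true = probs[np.arange(B)[:, None], np.arange(T)[None, :], targets]
    nll = -np.log(np.clip(p_true, 1e-300, None))
    loss = float((w * nll).sum())
    if not compute_grads:
        return loss, None
    return loss, model._backward(caches, targets, w)


def pretrain_step(
    model: PolicyNetwork,
    batch: Sequence[Trajectory],
    optimizer: Adam,
) -> float:
    """One supervised update: mean next-token NLL under teacher forcing.

    The model is trained as a multiclass classifier over the SMILES
    alphabet; returns the mean per-token cross-entropy before the update.
    """
    if not batch:
        raise ValueError("empty batch")
    _, _, mask = model.pad_batch(batch)
    n_tokens = mask.sum()
    weights = np.full(mask.shape, 1.0 / n_tokens)
    loss, grads = weighted_nll_and_grads(model, batch, weights)
    optimizer.step(grads)
    return loss


def trajectory_logprobs(model: PolicyNetwork, t: Trajectory) -> np.ndarray:
    """Per-step log p(s_i | s_{i-1}; theta), teacher-forced on t's prefix."""
    inputs, targets, _ = model.pad_batch([t])
    probs, _, _ = model._forward(inputs)
    N = len(t)
    p_true = probs[0, np.arange(N), targets[0, :N]]
    return np.log(np.clip(p_true, 1e-300, None))


def sample_trajectories(
    model: PolicyNetwork,
    n: int,
    seed: int,
    max_length: Optional[int] = None,
) -> List[Trajectory]:
    """Autoregressive multinomial sampling of n trajectories.

    Deterministic given the seed. Each trajectory ends with STOP unless
    it hits ``max_length`` first (then ``terminated`` is False).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    T = max_length if max_length is not None else model.max_length
    rng = np.random.default_rng(seed)
    h = np.zeros((n, model.hidden_size))
    x = np.full(n, model.vocab.start_id, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    seqs: List[List[int]] = [[] for _ in range(n)]
    for _ in range(T):
        probs, h, _ = model._step(x, h)
        u = rng.random(n)
        nxt = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        nxt = np.minimum(nxt, model.vocab.size - 1)
        for i in np.nonzero(alive)[0]:
            seqs[i].append(int(nxt[i]))
        alive &= nxt != model.vocab.stop_id
        if not alive.any():
            break
        x = nxt
    out: List[Trajectory] = []
    for ids in seqs:
        terminated = bool(ids) and ids[-1] == model.vocab.stop_id
        out.append(Trajectory(token_ids=tuple(ids), terminated=terminated))
    return out


def decode_samples(
    model: PolicyNetwork, trajectories: Sequence[Trajectory]
) -> List[str]:
    """SMILES strings for a batch of sampled trajectories."""
    return [model.vocab.decode_trajectory(t) for t in trajectories]


RewardFn = Callable[[str], float]


def pretrain(
    model: PolicyNetwork,
    corpus: Sequence[str],
    n_epochs: int = 20,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
    optimizer: Optional[Adam] = None,
) -> List[float]:
    """Supervised pretraining over a SMILES corpus.

    Shuffles each epoch and applies :func:`pretrain_step` per minibatch.
    Returns the mean per-token cross-entropy of each epoch.
    """
    if not corpus:
        raise ValueError("empty pretraining corpus")
    if optimizer is None:
        optimizer = Adam(model, lr=lr)
    trajectories = [model.vocab.encode_trajectory(s) for s in corpus]
    rng = np.random.default_rng(seed)
    epoch_losses: List[float] = []
    for _ in range(n_epochs):
        order = rng.permutation(len(trajectories))
        losses = []
        for start in range(0, len(order), batch_size):
            batch = [trajectories[i] for i in order[start : start + batch_size]]
            losses.append(pretrain_step(model, batch, optimizer))
        epoch_losses.append(float(np.mean(losses)))
    return epoch_losses
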