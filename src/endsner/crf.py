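"""Linear-chain conditional random field tagger.

The model scores a tag sequence y for a token sequence x as

    score(y | x) = sum_t  w_state . f(x, t, y_t)  +  sum_t  w_trans[y_{t-1}, y_t]

with binary indicator features f drawn from a fixed template family (token
identity, case shape, digit test, prefix/suffix, neighbor case shapes, and
BOS/EOS pseudo-features at sequence edges).  Training maximizes the
conditional log-likelihood penalized by an elastic net (l1·‖w‖₁ + l2·‖w‖²);
the smooth part is optimized with bound-constrained L-BFGS, the L1 term
handled exactly through the standard split-variable reformulation
w = w⁺ − w⁻ with w± ≥ 0.  Inference is exact: the forward recursion gives
the log partition function, forward–backward the posterior marginals, and
Viterbi the MAP tag sequence.

All inference is in log space with log-sum-exp stabilization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

from .preprocessing import (
    AnnotatedPost,
    ENTITY_LABELS,
    TagSequence,
    Token,
    encode_tags,
)

logger = logging.getLogger("endsner")


class EmptySequenceError(ValueError):
    """Inference was requested on a zero-length sequence."""


class ConfigurationError(ValueError):
    """Invalid training configuration or empty training corpus."""


def tag_set_for_scheme(scheme: str) -> list[str]:
    """Ordered tag list for a scheme; O first (the Viterbi tie-break winner)."""
    if scheme == "IO":
        prefixes = ["I"]
    elif scheme == "IOB":
        prefixes = ["B", "I"]
    elif scheme == "BILOU":
        prefixes = ["B", "I", "L", "U"]
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    return ["O"] + [f"{p}-{lbl}" for lbl in ENTITY_LABELS for p in prefixes]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for CRF training and feature extraction."""

    l1: float = 0.1
    l2: float = 0.1
    max_iterations: int = 100
    gradient_tolerance: float = 1e-5
    prefix_length: int = 3
    suffix_length: int = 3
    seed: int = 0
    scheme: str = "IO"

    def __post_init__(self) -> None:
        if self.l1 < 0 or self.l2 < 0:
            raise ConfigurationError("regularization strengths must be non-negative")
        if self.max_iterations < 1 or self.gradient_tolerance <= 0:
            raise ConfigurationError("invalid optimizer settings")
        if self.prefix_length < 1 or self.suffix_length < 1:
            raise ConfigurationError("affix lengths must be positive")


@dataclass
class CRFParams:
    """Trained weights: (feature, tag) state weights and tag-pair transitions."""

    tag_set: list[str]
    state_weights: dict[tuple[str, str], float]
    trans_weights: dict[tuple[str, str], float]


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def _shape_features(role: str, surface: str) -> list[str]:
    feats = []
    if surface.islower():
        feats.append(f"{role}.islower")
    if surface.isupper():
        feats.append(f"{role}.isupper")
    if surface.istitle():
        feats.append(f"{role}.istitle")
    return feats


def _surface_of(token) -> str:
    return token.surface if isinstance(token, Token) else str(token)


def extract_features(
    tokens: Sequence, position: int, config: TrainConfig = TrainConfig()
) -> list[str]:
    """Binary indicator features for one token position.

    Emits the token-identity feature, case-shape and digit indicators,
    prefix/suffix features, the case shapes of the previous and next tokens,
    and BOS/EOS pseudo-features at the sequence edges.
    """
    surface = _surface_of(tokens[position])
    lower = surface.lower()
    feats = [f"cur.lower={lower}"]
    feats += _shape_features("cur", surface)
    if surface.isdigit():
        feats.append("cur.isdigit")
    p, q = config.prefix_length, config.suffix_length
    feats.append(f"prefix{p}={lower[:p]}")
    feats.append(f"suffix{q}={lower[-q:]}")
    if position == 0:
        feats.append("BOS")
    else:
        feats += _shape_features("prev", _surface_of(tokens[position - 1]))
    if position == len(tokens) - 1:
        feats.append("EOS")
    else:
        feats += _shape_features("next", _surface_of(tokens[position + 1]))
    return feats


def extract_sequence_features(
    tokens: Sequence, config: TrainConfig = TrainConfig()
) -> list[list[str]]:
    return [extract_features(tokens, t, config) for t in range(len(tokens))]


# ---------------------------------------------------------------------------
# potentials and exact inference (single sequence, log domain)
# ---------------------------------------------------------------------------


def log_potentials(
    params: CRFParams, feature_sequence: Sequence[Sequence[str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Emission (T×L) and transition (L×L) log-score tables.

    ``emission[t, y]`` sums the state weights of the features active at
    position t for tag y; features unseen in training contribute zero.
    """
    tags = params.tag_set
    L = len(tags)
    emission = np.zeros((len(feature_sequence), L))
    for t, feats in enumerate(feature_sequence):
        for f in feats:
            for yi, y in enumerate(tags):
                w = params.state_weights.get((f, y))
                if w is not None:
                    emission[t, yi] += w
    transition = np.zeros((L, L))
    for yi, y in enumerate(tags):
        for zi, z in enumerate(tags):
            transition[yi, zi] = params.trans_weights.get((y, z), 0.0)
    return emission, transition


def _check_nonempty(emission: np.ndarray) -> None:
    if emission.shape[0] == 0:
        raise EmptySequenceError("inference requires at least one position")


def forward_log_partition(emission: np.ndarray, transition: np.ndarray) -> float:
    """log Z by the forward recursion (log-sum-exp stabilized)."""
    _check_nonempty(emission)
    alpha = emission[0].astype(float)
    for t in range(1, emission.shape[0]):
        alpha = logsumexp(alpha[:, None] + transition, axis=0) + emission[t]
    return float(logsumexp(alpha))


def backward_log_partition(emission: np.ndarray, transition: np.ndarray) -> float:
    """log Z by the backward recursion; agrees with the forward pass."""
    _check_nonempty(emission)
    L = emission.shape[1]
    beta = np.zeros(L)
    for t in range(emission.shape[0] - 2, -1, -1):
        beta = logsumexp(transition + (emission[t + 1] + beta)[None, :], axis=1)
    return float(logsumexp(emission[0] + beta))


def _forward_backward(emission: np.ndarray, transition: np.ndarray):
    T, L = emission.shape
    A = np.empty((T, L))
    A[0] = emission[0]
    for t in range(1, T):
        A[t] = logsumexp(A[t - 1][:, None] + transition, axis=0) + emission[t]
    B = np.zeros((T, L))
    for t in range(T - 2, -1, -1):
        B[t] = logsumexp(transition + (emission[t + 1] + B[t + 1])[None, :], axis=1)
    log_z = float(logsumexp(A[-1]))
    return A, B, log_z


def posterior_marginals(emission: np.ndarray, transition: np.ndarray) -> np.ndarray:
    """Per-position posterior tag probabilities, rows summing to one."""
    _check_nonempty(emission)
    A, B, log_z = _forward_backward(emission, transition)
    return np.exp(A + B - log_z)


def viterbi_path(emission: np.ndarray, transition: np.ndarray) -> list[int]:
    """MAP tag index sequence; ties resolve to the lowest tag index,
    earliest position first."""
    _check_nonempty(emission)
    T, L = emission.shape
    delta = emission[0].astype(float)
    back = np.zeros((T, L), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + transition
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(L)] + emission[t]
    path = [int(np.argmax(delta))]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


def viterbi_decode(
    params: CRFParams, tokens: Sequence, config: TrainConfig = TrainConfig()
) -> TagSequence:
    """Decode the most probable tag sequence for a token sequence."""
    if len(tokens) == 0:
        return TagSequence([], config.scheme)
    feats = extract_sequence_features(tokens, config)
    emission, transition = log_potentials(params, feats)
    path = viterbi_path(emission, transition)
    return TagSequence([params.tag_set[i] for i in path], config.scheme)


# ---------------------------------------------------------------------------
# training: packed dataset and penalized likelihood
# ---------------------------------------------------------------------------


class _Packed:
    """Dataset packed into a sparse feature matrix and padded index arrays."""

    def __init__(
        self,
        sequences: Sequence[tuple[Sequence[Sequence[str]], Sequence[str]]],
        feature_index: dict[str, int],
        tag_set: Sequence[str],
    ):
        tag_index = {y: i for i, y in enumerate(tag_set)}
        self.n_features = len(feature_index)
        self.n_tags = len(tag_set)
        lengths, gold, rows, cols = [], [], [], []
        pos = 0
        for feats_seq, tags in sequences:
            if len(feats_seq) != len(tags):
                raise ValueError("feature and tag sequences differ in length")
            lengths.append(len(feats_seq))
            for feats, tag in zip(feats_seq, tags):
                if tag not in tag_index:
                    raise ValueError(f"gold tag {tag!r} not in tag set {list(tag_set)}")
                gold.append(tag_index[tag])
                for f in feats:
                    fi = feature_index.get(f)
                    if fi is not None:
                        rows.append(pos)
                        cols.append(fi)
                pos += 1
        self.lengths = np.array(lengths, dtype=np.intp)
        self.gold = np.array(gold, dtype=np.intp)
        self.n_pos = pos
        data = np.ones(len(rows))
        self.X = sp.csr_matrix(
            (data, (rows, cols)), shape=(pos, self.n_features)
        )
        n, t_max = len(lengths), int(self.lengths.max(initial=1))
        self.mask = np.arange(t_max)[None, :] < self.lengths[:, None]
        self.t_max = t_max
        # empirical transition counts
        self.trans_counts = np.zeros((self.n_tags, self.n_tags))
        offset = 0
        for ln in lengths:
            seq = self.gold[offset : offset + ln]
            np.add.at(self.trans_counts, (seq[:-1], seq[1:]), 1.0)
            offset += ln


def _smooth_nll_grad(W: np.ndarray, trans: np.ndarray, packed: _Packed):
    """Unpenalized NLL and its gradient over a packed dataset (batched)."""
    n_seq = len(packed.lengths)
    t_max, L = packed.t_max, packed.n_tags
    emission_flat = np.asarray(packed.X @ W)
    E = np.zeros((n_seq, t_max, L))
    E[packed.mask] = emission_flat

    A = np.empty((n_seq, t_max, L))
    A[:, 0] = E[:, 0]
    for t in range(1, t_max):
        new = logsumexp(A[:, t - 1][:, :, None] + trans[None], axis=1) + E[:, t]
        active = packed.mask[:, t]
        A[:, t] = np.where(active[:, None], new, A[:, t - 1])
    log_z = logsumexp(A[:, -1], axis=1)

    B = np.zeros((n_seq, t_max, L))
    for t in range(t_max - 2, -1, -1):
        nxt = E[:, t + 1] + B[:, t + 1]
        new = logsumexp(trans[None] + nxt[:, None, :], axis=2)
        B[:, t] = np.where(packed.mask[:, t + 1][:, None], new, 0.0)

    marg_flat = np.exp((A + B - log_z[:, None, None])[packed.mask])

    exp_trans = np.zeros((L, L))
    for t in range(t_max - 1):
        valid = packed.mask[:, t + 1]
        if not valid.any():
            continue
        contrib = np.exp(
            A[valid, t][:, :, None]
            + trans[None]
            + (E[valid, t + 1] + B[valid, t + 1])[:, None, :]
            - log_z[valid][:, None, None]
        )
        exp_trans += contrib.sum(axis=0)

    idx = np.arange(packed.n_pos)
    gold_score = emission_flat[idx, packed.gold].sum() + (packed.trans_counts * trans).sum()
    nll = float(log_z.sum() - gold_score)

    diff = marg_flat
    diff[idx, packed.gold] -= 1.0
    g_state = np.asarray(packed.X.T @ diff)
    g_trans = exp_trans - packed.trans_counts
    return nll, g_state, g_trans


def _optimize(packed: _Packed, config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    F, L = packed.n_features, packed.n_tags
    dim = F * L + L * L

    def unpack(theta: np.ndarray):
        return theta[: F * L].reshape(F, L), theta[F * L :].reshape(L, L)

    def smooth(theta: np.ndarray):
        W, trans = unpack(theta)
        nll, g_state, g_trans = _smooth_nll_grad(W, trans, packed)
        nll += config.l2 * float(theta @ theta)
        grad = np.concatenate([g_state.ravel(), g_trans.ravel()]) + 2.0 * config.l2 * theta
        return nll, grad

    options = {
        "maxiter": config.max_iterations,
        "gtol": config.gradient_tolerance,
        "ftol": 1e-12,
        "maxfun": 20 * config.max_iterations,
    }
    if config.l1 > 0:
        # exact elastic net via w = u - v, u,v >= 0, penalty l1·sum(u+v)
        def objective(uv: np.ndarray):
            u, v = uv[:dim], uv[dim:]
            val, grad = smooth(u - v)
            val += config.l1 * float(uv.sum())
            return val, np.concatenate([grad + config.l1, -grad + config.l1])

        res = scipy.optimize.minimize(
            objective,
            np.zeros(2 * dim),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * dim),
            options=options,
        )
        theta = res.x[:dim] - res.x[dim:]
    else:
        res = scipy.optimize.minimize(
            smooth, np.zeros(dim), jac=True, method="L-BFGS-B", options=options
        )
        theta = res.x
    if not res.success:
        logger.warning("CRF optimizer stopped before convergence: %s", res.message)
    return theta[: F * L].reshape(F, L), theta[F * L :].reshape(L, L)


def nll_and_gradient(
    params: CRFParams,
    dataset: Sequence[tuple[Sequence[Sequence[str]], Sequence[str]]],
    config: TrainConfig = TrainConfig(),
) -> tuple[float, dict[tuple, float]]:
    """Penalized negative log-likelihood and the gradient of its smooth part.

    The value includes the full elastic-net penalty
    ``l1·‖w‖₁ + l2·‖w‖²``; the returned gradient covers the smooth part only
    (log-likelihood plus the L2 term), keyed ``("state", feature, tag)`` and
    ``("trans", tag_from, tag_to)``.
    """
    feature_names = sorted(
        {f for feats_seq, _ in dataset for feats in feats_seq for f in feats}
        | {f for (f, _) in params.state_weights}
    )
    findex = {f: i for i, f in enumerate(feature_names)}
    packed = _Packed(dataset, findex, params.tag_set)
    W = np.zeros((len(findex), len(params.tag_set)))
    tindex = {y: i for i, y in enumerate(params.tag_set)}
    for (f, y), w in params.state_weights.items():
        W[findex[f], tindex[y]] = w
    trans = np.zeros((len(params.tag_set),) * 2)
    for (y, z), w in params.trans_weights.items():
        trans[tindex[y], tindex[z]] = w
    nll, g_state, g_trans = _smooth_nll_grad(W, trans, packed)
    sq = float((W**2).sum() + (trans**2).sum())
    l1 = float(np.abs(W).sum() + np.abs(trans).sum())
    value = nll + config.l2 * sq + config.l1 * l1
    grad: dict[tuple, float] = {}
    for f, fi in findex.items():
        for y, yi in tindex.items():
            grad[("state", f, y)] = float(g_state[fi, yi] + 2 * config.l2 * W[fi, yi])
    for y, yi in tindex.items():
        for z, zi in tindex.items():
            grad[("trans", y, z)] = float(g_trans[yi, zi] + 2 * config.l2 * trans[yi, zi])
    return value, grad


# ---------------------------------------------------------------------------
# the tagger
# ---------------------------------------------------------------------------


@runtime_checkable
class Tagger(Protocol):
    """Contract for pluggable sequence taggers."""

    def fit(self, corpus: Sequence[AnnotatedPost]) -> "Tagger": ...

    def predict(self, tokens: Sequence[Token]) -> TagSequence: ...


class CRFTagger:
    """Linear-chain CRF tagger with the fixed feature template family.

    The feature space is built from the training corpus only; features unseen
    at prediction time contribute zero score.
    """

    MODEL_FORMAT_VERSION = 1

    def __init__(self, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.tag_set = tag_set_for_scheme(self.config.scheme)
        self.feature_index: dict[str, int] = {}
        self.W = np.zeros((0, len(self.tag_set)))
        self.trans = np.zeros((len(self.tag_set),) * 2)

    # -- training ----------------------------------------------------------

    def fit(self, corpus: Sequence[AnnotatedPost]) -> "CRFTagger":
        if not corpus:
            raise ConfigurationError("training corpus is empty")
        sequences = []
        for post in corpus:
            if not post.tokens:
                continue
            feats_seq = extract_sequence_features(post.tokens, self.config)
            tags = encode_tags(post.tokens, post.spans, self.config.scheme)
            sequences.append((feats_seq, list(tags)))
        if not sequences:
            raise ConfigurationError("training corpus contains no non-empty posts")
        names = sorted({f for feats_seq, _ in sequences for feats in feats_seq for f in feats})
        self.feature_index = {f: i for i, f in enumerate(names)}
        packed = _Packed(sequences, self.feature_index, self.tag_set)
        self.W, self.trans = _optimize(packed, self.config)
        return self

    # -- prediction --------------------------------------------------------

    def _emission(self, feats_seq: Sequence[Sequence[str]]) -> np.ndarray:
        emission = np.zeros((len(feats_seq), len(self.tag_set)))
        for t, feats in enumerate(feats_seq):
            for f in feats:
                fi = self.feature_index.get(f)
                if fi is not None:
                    emission[t] += self.W[fi]
        return emission

    def predict(self, tokens: Sequence[Token]) -> TagSequence:
        if len(tokens) == 0:
            return TagSequence([], self.config.scheme)
        feats_seq = extract_sequence_features(tokens, self.config)
        path = viterbi_path(self._emission(feats_seq), self.trans)
        return TagSequence([self.tag_set[i] for i in path], self.config.scheme)

    # -- parameter views and serialization ---------------------------------

    @property
    def params(self) -> CRFParams:
        state = {}
        for f, fi in self.feature_index.items():
            for yi, y in enumerate(self.tag_set):
                w = float(self.W[fi, yi])
                if w != 0.0:
                    state[(f, y)] = w
        trans = {}
        for yi, y in enumerate(self.tag_set):
            for zi, z in enumerate(self.tag_set):
                w = float(self.trans[yi, zi])
                if w != 0.0:
                    trans[(y, z)] = w
        return CRFParams(list(self.tag_set), state, trans)

    def to_dict(self) -> dict:
        params = self.params
        state: dict[str, dict[str, float]] = {}
        for (f, y), w in params.state_weights.items():
            state.setdefault(f, {})[y] = w
        trans: dict[str, dict[str, float]] = {}
        for (y, z), w in params.trans_weights.items():
            trans.setdefault(y, {})[z] = w
        return {
            "format_version": self.MODEL_FORMAT_VERSION,
            "tag_set": list(self.tag_set),
            "state_weights": state,
            "trans_weights": trans,
            "config": asdict(self.config),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "CRFTagger":
        if obj.get("format_version") != cls.MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {obj.get('format_version')!r}")
        tagger = cls(TrainConfig(**obj["config"]))
        tagger.tag_set = list(obj["tag_set"])
        names = sorted(obj["state_weights"])
        tagger.feature_index = {f: i for i, f in enumerate(names)}
        tagger.W = np.zeros((len(names), len(tagger.tag_set)))
        tindex = {y: i for i, y in enumerate(tagger.tag_set)}
        for f, per_tag in obj["state_weights"].items():
            for y, w in per_tag.items():
                tagger.W[tagger.feature_index[f], tindex[y]] = w
        tagger.trans = np.zeros((len(tagger.tag_set),) * 2)
        for y, per_to in obj["trans_weights"].items():
            for z, w in per_to.items():
                tagger.trans[tindex[y], tindex[z]] = w
        return tagger

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), ensure_ascii=False), "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CRFTagger":
        return cls.from_dict(json.loads(Path(path).read_text("utf-8")))


def train_crf(corpus: Sequence[AnnotatedPost], config: TrainConfig = TrainConfig()) -> CRFParams:
    """Train a CRF on an annotated corpus and return its parameters."""
    return CRFTagger(config).fit(corpus).params
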