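"""Discrete flow matching over the 21-token state space (20 amino acids + MASK).

The forward corruption linearly interpolates between the fully masked state at
t = 0 and the native sequence at t = 1: each position independently keeps its
native token with probability t.  Sampling reverses this along the masked-CTMC
rate: a position still masked at time t unmasks during the next step of size
dt with probability dt / (1 - t), drawing its token from the model's softmax
at temperature tau (excluded tokens renormalised away).  Unmasked tokens never
re-mask, so a uniform 10-step schedule fully decodes any length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, log_softmax
from .utils import AA_TO_INDEX, MASK_TOKEN, seed_stream, string_to_tokens, tokens_to_string

__all__ = [
    "FlowState",
    "SamplerConfig",
    "DesignResult",
    "corrupt",
    "fm_loss",
    "sampler_step",
    "design_sequences",
    "temperature_limit_decode",
]

ARGMAX_TEMPERATURE = 1e-4  # below this, sampling degenerates to restricted argmax


@dataclass
class FlowState:
    """Partially masked token sequence at flow time t."""

    tokens: np.ndarray  # (L,) int in {0..19, MASK_TOKEN}
    t: float

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if not (0.0 <= self.t <= 1.0 + 1e-9):
            raise ValueError("flow time must lie in [0, 1]")
        if self.tokens.size and (self.tokens.min() < 0 or self.tokens.max() > MASK_TOKEN):
            raise ValueError("invalid token value")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def masked(self) -> np.ndarray:
        return self.tokens == MASK_TOKEN

    def sequence(self) -> str:
        return tokens_to_string(self.tokens)


@dataclass
class SamplerConfig:
    """Few-step parallel sampler settings."""

    n_steps: int = 10
    temperature: float = 0.1
    excluded_tokens: frozenset = frozenset()
    fixed_positions: dict = field(default_factory=dict)  # index -> token or letter
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        excluded = set()
        for tok in self.excluded_tokens:
            excluded.add(AA_TO_INDEX[tok] if isinstance(tok, str) else int(tok))
        if not all(0 <= e < MASK_TOKEN for e in excluded):
            raise ValueError("excluded tokens must be amino acids")
        self.excluded_tokens = frozenset(excluded)
        fixed = {}
        for pos, tok in self.fixed_positions.items():
            tok = AA_TO_INDEX[tok] if isinstance(tok, str) else int(tok)
            if not 0 <= tok < MASK_TOKEN:
                raise ValueError("fixed tokens must be amino acids")
            fixed[int(pos)] = tok
        self.fixed_positions = fixed
        if len(self.excluded_tokens) >= MASK_TOKEN:
            raise ValueError("cannot exclude every amino acid")

    @classmethod
    def omit_cys(cls, **kwargs) -> "SamplerConfig":
        """The binder-design default: cysteine excluded from generation."""
        return cls(excluded_tokens=frozenset({"C"}), **kwargs)


@dataclass
class DesignResult:
    sequences: list[str]
    scores: list[float]               # mean log-probability at unmasking time
    unmask_trajectories: list[list[int]]  # newly unmasked count per step


def corrupt(native_tokens, t: float, seed: int = 0,
            rng: np.random.Generator | None = None) -> FlowState:
    """Forward corruption: keep each native token with probability t, else MASK."""
    if isinstance(native_tokens, str):
        native_tokens = string_to_tokens(native_tokens)
    native_tokens = np.asarray(native_tokens, dtype=np.int64)
    if native_tokens.size and (native_tokens.min() < 0 or native_tokens.max() >= MASK_TOKEN):
        raise ValueError("native tokens must be amino acids")
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    if rng is None:
        rng = seed_stream(seed, "corrupt")
    keep = rng.uniform(size=native_tokens.shape) < t
    tokens = np.where(keep, native_tokens, MASK_TOKEN)
    return FlowState(tokens=tokens, t=t)


def fm_loss(logits, native_tokens, mask_positions=None):
    """Mean cross-entropy between logits and the native sequence.

    ``mask_positions`` selects the positions entering the mean (training uses
    the corrupted/masked set); ``None`` means all positions.  An empty
    selection is defined as 0 with a warning.  Returns a Tensor when ``logits``
    is a Tensor so gradients flow.
    """
    if isinstance(native_tokens, str):
        native_tokens = string_to_tokens(native_tokens)
    native_tokens = np.asarray(native_tokens, dtype=np.int64)
    is_tensor = isinstance(logits, Tensor)
    lo = logits if is_tensor else Tensor(np.asarray(logits, dtype=float))
    if lo.shape[0] != native_tokens.shape[0]:
        raise ValueError("logits/native length mismatch")
    if mask_positions is None:
        sel = np.arange(len(native_tokens))
    else:
        mask_positions = np.asarray(mask_positions)
        sel = np.nonzero(mask_positions)[0] if mask_positions.dtype == bool else mask_positions
    if sel.size == 0:
        warnings.warn("fm_loss over an empty selection; defined as 0")
        return Tensor(0.0) if is_tensor else 0.0
    logp = log_softmax(lo, axis=-1)
    picked = logp[sel, native_tokens[sel]]
    loss = -picked.mean()
    return loss if is_tensor else float(loss.data)


def _token_probabilities(logits: np.ndarray, cfg: SamplerConfig) -> np.ndarray:
    """softmax(logits / tau) with excluded tokens removed and renormalised.

    Temperatures below the argmax threshold return a one-hot on the best
    allowed token (the exact tau -> 0 limit, computed without underflow).
    """
    logits = np.asarray(logits, dtype=float)
    if len(cfg.excluded_tokens) >= logits.shape[-1]:
        raise ValueError("all tokens excluded")
    if cfg.temperature < ARGMAX_TEMPERATURE:
        restricted = logits.copy()
        if cfg.excluded_tokens:
            restricted[:, list(cfg.excluded_tokens)] = -np.inf
        p = np.zeros_like(logits)
        p[np.arange(len(logits)), restricted.argmax(axis=-1)] = 1.0
        return p
    z = logits / cfg.temperature
    z = z - z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    if cfg.excluded_tokens:
        p[:, list(cfg.excluded_tokens)] = 0.0
    total = p.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("all tokens excluded at some position")
    return p / total


def sampler_step(state: FlowState, logits, dt: float, cfg: SamplerConfig,
                 rng: np.random.Generator | int | None = None) -> FlowState:
    """One parallel unmasking step of the reverse CTMC.

    Each masked position unmasks with probability min(1, dt / (1 - t)); an
    unmasking position draws from the temperature-sharpened, exclusion-
    renormalised distribution (argmax when the temperature is below 1e-4).
    Already-unmasked positions never change.
    """
    if state.t + dt > 1.0 + 1e-9:
        raise ValueError("step exceeds t = 1")
    logits = np.asarray(logits.data if isinstance(logits, Tensor) else logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = seed_stream(cfg.seed if rng is None else int(rng), "sampler-step")
    remaining = 1.0 - state.t
    p_unmask = 1.0 if remaining <= dt + 1e-9 else min(1.0, dt / remaining)
    masked_idx = np.nonzero(state.masked)[0]
    tokens = state.tokens.copy()
    if masked_idx.size:
        unmask = rng.uniform(size=masked_idx.size) < p_unmask
        chosen = masked_idx[unmask]
        if chosen.size:
            probs = _token_probabilities(logits[chosen], cfg)
            if cfg.temperature < ARGMAX_TEMPERATURE:
                tokens[chosen] = probs.argmax(axis=-1)
            else:
                u = rng.uniform(size=chosen.size)
                cum = probs.cumsum(axis=-1)
                tokens[chosen] = (u[:, None] > cum).sum(axis=-1)
    return FlowState(tokens=tokens, t=min(state.t + dt, 1.0))


def _initial_state(length: int, cfg: SamplerConfig) -> FlowState:
    tokens = np.full(length, MASK_TOKEN, dtype=np.int64)
    for pos, tok in cfg.fixed_positions.items():
        if not 0 <= pos < length:
            raise IndexError(f"fixed position {pos} out of range")
        tokens[pos] = tok
    return FlowState(tokens=tokens, t=0.0)


def design_sequences(bb, model, n_samples: int, cfg: SamplerConfig,
                     noise_level: str = "clean") -> DesignResult:
    """Sample full sequences for a backbone with the few-step parallel sampler.

    The backbone-only pair embedding is computed once (`model.cache_pair`) and
    reused at every step and for every sample.  Fixed positions are placed in
    the initial state and never revisited; every returned sequence is fully
    unmasked.
    """
    cached = model.cache_pair(bb)
    dt = 1.0 / cfg.n_steps
    master = seed_stream(cfg.seed, "design-sequences")
    sequences, scores, trajectories = [], [], []
    for _ in range(n_samples):
        state = _initial_state(len(bb), cfg)
        rng = np.random.default_rng(master.integers(2**31 - 1))
        logp_sum, logp_n = 0.0, 0
        steps = []
        for _ in range(cfg.n_steps):
            if not state.masked.any():
                steps.append(0)
                state = replace(state, t=min(state.t + dt, 1.0))
                continue
            logits = model.logits(bb, state, cached=cached, noise_level=noise_level)
            logits = np.asarray(logits.data if isinstance(logits, Tensor) else logits)
            before = state.masked.copy()
            state = sampler_step(state, logits, dt, cfg, rng=rng)
            newly = before & ~state.masked
            steps.append(int(newly.sum()))
            if newly.any():
                probs = _token_probabilities(logits[newly], cfg)
                picked = probs[np.arange(newly.sum()), state.tokens[newly]]
                logp_sum += float(np.log(np.maximum(picked, 1e-300)).sum())
                logp_n += int(newly.sum())
        if state.masked.any():  # pragma: no cover - schedule guarantees completion
            raise RuntimeError("sampler finished with masked positions")
        sequences.append(state.sequence())
        scores.append(logp_sum / max(logp_n, 1))
        trajectories.append(steps)
    return DesignResult(sequences=sequences, scores=scores, unmask_trajectories=trajectories)


def temperature_limit_decode(bb, model, cfg: SamplerConfig | None = None,
                             noise_level: str = "clean") -> str:
    """Deterministic zero-temperature decode.

    Fully seed-independent: each step unmasks its share of the remaining
    masked positions (the uniform schedule's expectation), choosing the
    positions where the model is most confident, and assigns the restricted
    argmax token.  This is the tau -> 0 limit of the stochastic sampler with
    the timing randomness replaced by a confidence ordering.
    """
    cfg = cfg or SamplerConfig()
    cached = model.cache_pair(bb)
    state = _initial_state(len(bb), cfg)
    for step in range(cfg.n_steps):
        masked_idx = np.nonzero(state.masked)[0]
        if masked_idx.size == 0:
            break
        steps_left = cfg.n_steps - step
        m = int(np.ceil(masked_idx.size / steps_left))
        logits = model.logits(bb, state, cached=cached, noise_level=noise_level)
        logits = np.asarray(logits.data if isinstance(logits, Tensor) else logits)
        argmax_cfg = replace(cfg, temperature=ARGMAX_TEMPERATURE / 2)
        probs = _token_probabilities(logits[masked_idx], argmax_cfg)
        conf = probs.max(axis=-1)
        # most confident first; ties resolved by position index for determinism
        order = np.lexsort((masked_idx, -conf))[:m]
        chosen = masked_idx[order]
        tokens = state.tokens.copy()
        tokens[chosen] = probs[order].argmax(axis=-1)
        state = FlowState(tokens=tokens, t=min(state.t + 1.0 / cfg.n_steps, 1.0))
    if state.masked.any():  # pragma: no cover
        raise RuntimeError("decode finished with masked positions")
    return state.sequence()
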