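"""GRU temporal forecaster with genetic-algorithm optimization.

Links environmental-series history and daily case history to the next day's
indicator case count: sliding windows of (y, x) history of length ``window``
map to the next-step value y'_t = F(y_1..y_{t-1}, x_1..x_{t-1}).  The
recurrent cell is a gated recurrent unit,

    r_t = sigma(W_r x_t + U_r h_{t-1})            (reset gate)
    z_t = sigma(W_z x_t + U_z h_{t-1})            (update gate)
    h~_t = tanh(U x_t + W (r_t . h_{t-1}) + b_h)  (candidate)
    h_t = z_t . h_{t-1} + (1 - z_t) . h~_t

with the convention that z_t -> 1 preserves the previous hidden state.
Training uses Adam on the mean squared error.

A real-coded genetic algorithm wraps the forecaster: each genome encodes an
input-feature inclusion mask (threshold 0.5), the hidden size and the
learning rate (log scale).  Fitness is the validation MSE E(y_i); selection
is inverse-fitness roulette P_s(i) = (1/E_i) / sum_j (1/E_j); crossover
swaps positions between the two real-coded parents; position mutation
resamples an element uniformly on its slot bounds (the draw is regenerated
until it is not less than the mutation probability, which biases accepted
draws upward — an ``unbiased_mutation`` flag substitutes a plain uniform
draw).  Elitism makes the best-fitness trace monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit as sigmoid

from ._nn import Adam


# ---------------------------------------------------------------------------
# GRU cell


@dataclass
class GRUParams:
    """Gate and candidate weights of one GRU cell (no gate biases; the
    candidate carries the single bias b_h, matching the cell definition)."""

    Wr: np.ndarray
    Ur: np.ndarray
    Wz: np.ndarray
    Uz: np.ndarray
    U: np.ndarray
    W: np.ndarray
    bh: np.ndarray

    @classmethod
    def init(cls, n_in: int, hidden: int, rng) -> "GRUParams":
        s_in = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / hidden)
        return cls(
            Wr=rng.uniform(-s_in, s_in, (hidden, n_in)),
            Ur=rng.uniform(-s_h, s_h, (hidden, hidden)),
            Wz=rng.uniform(-s_in, s_in, (hidden, n_in)),
            Uz=rng.uniform(-s_h, s_h, (hidden, hidden)),
            U=rng.uniform(-s_in, s_in, (hidden, n_in)),
            W=rng.uniform(-s_h, s_h, (hidden, hidden)),
            bh=np.zeros(hidden),
        )

    @property
    def hidden(self) -> int:
        return self.Ur.shape[0]

    def arrays(self) -> list[np.ndarray]:
        return [self.Wr, self.Ur, self.Wz, self.Uz, self.U, self.W, self.bh]


@dataclass
class GRUState:
    """Per-step quantities of one GRU update."""

    r: np.ndarray
    z: np.ndarray
    h_tilde: np.ndarray
    h: np.ndarray


def gru_step(params: GRUParams, x_t: np.ndarray, h_prev: np.ndarray
             ) -> GRUState:
    """One GRU update.  ``x_t`` may be (n_in,) or (batch, n_in), ``h_prev``
    correspondingly (H,) or (batch, H).  Gates lie in (0, 1), the candidate
    in (-1, 1), and h_t is a convex combination of h_prev and the candidate
    (so z -> 1 preserves the previous state)."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if not (np.isfinite(x_t).all() and np.isfinite(h_prev).all()):
        raise ValueError("non-finite inputs to gru_step")
    r = sigmoid(x_t @ params.Wr.T + h_prev @ params.Ur.T)
    z = sigmoid(x_t @ params.Wz.T + h_prev @ params.Uz.T)
    h_tilde = np.tanh(x_t @ params.U.T + (r * h_prev) @ params.W.T + params.bh)
    h = z * h_prev + (1.0 - z) * h_tilde
    return GRUState(r=r, z=z, h_tilde=h_tilde, h=h)


# ---------------------------------------------------------------------------
# fitness and GA operators


def fitness(predictions, targets) -> float:
    """Mean squared error E(y) = (1/n) sum (y'_i - y_i)^2."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.size == 0 or p.shape != t.shape:
        raise ValueError("predictions and targets must be aligned, non-empty")
    return float(np.mean((p - t) ** 2))


def population_fitness(individual_fitnesses) -> float:
    """Total population fitness f = sum_i E(y_i)."""
    return float(np.sum(np.asarray(individual_fitnesses, dtype=float)))


def roulette_probabilities(fitnesses) -> np.ndarray:
    """Inverse-fitness selection probabilities P_s(i) = (1/E_i)/sum(1/E_j);
    lower MSE means more likely.  Zero fitnesses get epsilon = 1e-12."""
    E = np.asarray(fitnesses, dtype=float)
    if E.size == 0:
        raise ValueError("empty population")
    inv = 1.0 / np.maximum(E, 1e-12)
    return inv / inv.sum()


def roulette_select(fitnesses, rng) -> int:
    """Draw one index with inverse-fitness roulette probabilities."""
    p = roulette_probabilities(fitnesses)
    return int(rng.choice(len(p), p=p))


def real_crossover(parent_a: np.ndarray, parent_b: np.ndarray,
                   crossover_prob: float, rng
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Position-exchange crossover for real-coded genomes: each position is
    swapped between the parents with probability ``crossover_prob``."""
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parent genomes must have equal length")
    swap = rng.random(a.shape) < crossover_prob
    child_a, child_b = a.copy(), b.copy()
    child_a[swap], child_b[swap] = b[swap], a[swap]
    return child_a, child_b


def position_mutate(genome: np.ndarray, lo, hi, mutation_prob: float, rng,
                    per_element_prob: float | None = None,
                    unbiased: bool = False) -> np.ndarray:
    """Position mutation H'_k = H_min + (H_max - H_min) * rand01.

    The uniform draw is regenerated until it is not less than the mutation
    probability, then used to place the new value within the slot bounds
    (``unbiased=True`` uses a plain uniform draw instead).  By default every
    element is resampled; ``per_element_prob`` restricts mutation to a
    random subset of positions, leaving the rest untouched.
    """
    g = np.asarray(genome, dtype=float).copy()
    lo = np.broadcast_to(np.asarray(lo, dtype=float), g.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), g.shape)
    if (lo > hi).any():
        raise ValueError("slot lower bound exceeds upper bound")
    if per_element_prob is None:
        sel = np.ones(g.shape, dtype=bool)
    else:
        sel = rng.random(g.shape) < per_element_prob
    for k in np.flatnonzero(sel):
        d = rng.random()
        if not unbiased:
            while d < mutation_prob:
                d = rng.random()
        g[k] = lo[k] + (hi[k] - lo[k]) * d
    return g


# ---------------------------------------------------------------------------
# forecaster


@dataclass
class ForecastSpec:
    """Windowed next-step supervision: length-``window`` histories of the
    target (daily case counts) and exposure channels predict the next day."""

    window: int = 7
    horizon: int = 1

    def __post_init__(self):
        if self.window < 1 or self.horizon != 1:
            raise ValueError("window must be >= 1 and horizon must be 1")


def _build_windows(y: np.ndarray, X: np.ndarray | None, window: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stack (y, x) histories: sequences (n, window, d) and targets (n,)."""
    T = len(y)
    if T <= window:
        raise ValueError("series shorter than the history window")
    feats = y[:, None] if X is None else np.column_stack([y, X])
    seqs = np.stack([feats[t - window:t] for t in range(window, T)])
    targets = y[window:]
    return seqs, targets


@dataclass
class GRUResults:
    """Fitted forecaster: parameters, training history, predictions."""

    model: "GRUForecaster"
    params: GRUParams
    w_out: np.ndarray
    b_out: float
    history: pd.DataFrame
    converged_epoch: int

    def forecast(self, y=None, exog=None) -> np.ndarray:
        """Next-step predictions for a series (defaults to the training
        series), aligned to the target timestamps."""
        m = self.model
        y = m.y if y is None else np.asarray(y, dtype=float)
        X = (m.exog if exog is None
             else np.atleast_2d(np.asarray(exog, dtype=float).T).T)
        seqs, _ = _build_windows((y - m._y_mean) / m._y_scale,
                                 None if X is None
                                 else (X - m._x_mean) / m._x_scale,
                                 m.spec.window)
        preds = self.model._forward_batch(self.params, self.w_out,
                                          self.b_out, seqs)
        return preds * m._y_scale + m._y_mean

    def summary(self) -> str:
        m = self.model
        return "\n".join([
            "GRU forecaster (next-step, Adam on MSE)",
            f"  window: {m.spec.window}   hidden units: {m.hidden}   "
            f"inputs/step: {m.n_in}",
            f"  epochs run: {len(self.history)}   "
            f"final train MSE: {self.history['mse'].iloc[-1]:.5f}",
        ])


class GRUForecaster:
    """Model object for the GA-GRU stage: built from a target series and
    optional exposure channels; ``fit`` trains with Adam and returns
    :class:`GRUResults`.

    Inputs are standardized internally; predictions are returned on the
    original scale.
    """

    def __init__(self, y, exog=None, spec: ForecastSpec | None = None,
                 hidden: int = 16, learning_rate: float = 0.01):
        self.y = np.asarray(y, dtype=float)
        self.exog = None if exog is None else np.atleast_2d(
            np.asarray(exog, dtype=float).T).T
        if self.exog is not None and len(self.exog) != len(self.y):
            raise ValueError("y and exog must be aligned")
        self.spec = spec or ForecastSpec()
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.n_in = 1 + (0 if self.exog is None else self.exog.shape[1])
        self._y_mean = self.y.mean()
        self._y_scale = self.y.std() or 1.0
        if self.exog is not None:
            self._x_mean = self.exog.mean(axis=0)
            self._x_scale = np.where(self.exog.std(axis=0) == 0.0, 1.0,
                                     self.exog.std(axis=0))

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def _forward_batch(params: GRUParams, w_out, b_out, seqs: np.ndarray
                       ) -> np.ndarray:
        h = np.zeros((len(seqs), params.hidden))
        for t in range(seqs.shape[1]):
            h = gru_step(params, seqs[:, t], h).h
        return h @ w_out + b_out

    def _forward_cache(self, params, seqs):
        h = np.zeros((len(seqs), params.hidden))
        cache = []
        for t in range(seqs.shape[1]):
            st = gru_step(params, seqs[:, t], h)
            cache.append((seqs[:, t], h, st))
            h = st.h
        return h, cache

    @staticmethod
    def _backward(params, cache, dh, grads):
        gWr, gUr, gWz, gUz, gU, gW, gbh = grads
        for x_t, h_prev, st in reversed(cache):
            dz = dh * (h_prev - st.h_tilde) * st.z * (1.0 - st.z)
            dht = dh * (1.0 - st.z)
            da = dht * (1.0 - st.h_tilde ** 2)
            gU += da.T @ x_t
            gW += da.T @ (st.r * h_prev)
            gbh += da.sum(axis=0)
            wda = da @ params.W
            dr = wda * h_prev * st.r * (1.0 - st.r)
            gWr += dr.T @ x_t
            gUr += dr.T @ h_prev
            gWz += dz.T @ x_t
            gUz += dz.T @ h_prev
            dh = (dh * st.z + wda * st.r + dr @ params.Ur + dz @ params.Uz)

    # -- training ----------------------------------------------------------

    def fit(self, epochs: int = 100, batch_size: int = 64, seed: int = 0,
            val_fraction: float = 0.0, patience: int | None = None
            ) -> GRUResults:
        """Train with Adam on the MSE.  With ``val_fraction`` > 0 the tail
        of the series is held out chronologically and ``patience`` stops
        training after that many epochs without validation improvement."""
        rng = np.random.default_rng(seed)
        y_std = (self.y - self._y_mean) / self._y_scale
        X_std = (None if self.exog is None
                 else (self.exog - self._x_mean) / self._x_scale)
        seqs, targets = _build_windows(y_std, X_std, self.spec.window)
        n = len(seqs)
        n_val = int(round(n * val_fraction))
        if n_val:
            tr_s, tr_t = seqs[:-n_val], targets[:-n_val]
            va_s, va_t = seqs[-n_val:], targets[-n_val:]
        else:
            tr_s, tr_t = seqs, targets
            va_s = va_t = None

        params = GRUParams.init(self.n_in, self.hidden, rng)
        w_out = rng.uniform(-0.1, 0.1, self.hidden)
        b_out = np.zeros(1)
        arrays = params.arrays() + [w_out, b_out]
        grads = [np.zeros_like(a) for a in arrays]
        opt = Adam(arrays, grads, lr=self.learning_rate)

        rows, best_val, best_epoch, stale = [], np.inf, 0, 0
        best_state = None
        for epoch in range(epochs):
            order = rng.permutation(len(tr_s))
            ep_loss, n_b = 0.0, 0
            for start in range(0, len(tr_s), batch_size):
                idx = order[start:start + batch_size]
                sb, tb = tr_s[idx], tr_t[idx]
                for g in grads:
                    g[...] = 0.0
                h, cache = self._forward_cache(params, sb)
                pred = h @ w_out + b_out[0]
                err = pred - tb
                loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError("non-finite training loss; lower the "
                                       "learning rate")
                dpred = 2.0 * err / len(tb)
                grads[-2][...] = h.T @ dpred
                grads[-1][...] = dpred.sum()
                self._backward(params, cache, np.outer(dpred, w_out),
                               grads[:7])
                opt.step()
                ep_loss += loss
                n_b += 1
            row = {"epoch": epoch + 1, "mse": ep_loss / n_b}
            if va_s is not None:
                val_pred = self._forward_batch(params, w_out, b_out[0], va_s)
                row["val_mse"] = fitness(val_pred, va_t)
                if row["val_mse"] < best_val - 1e-12:
                    best_val, best_epoch, stale = row["val_mse"], epoch, 0
                    best_state = ([a.copy() for a in params.arrays()],
                                  w_out.copy(), float(b_out[0]))
                else:
                    stale += 1
            rows.append(row)
            if patience is not None and va_s is not None and stale >= patience:
                break
        if best_state is not None:
            for a, best in zip(params.arrays(), best_state[0]):
                a[...] = best
            w_out[...] = best_state[1]
            b_out[0] = best_state[2]
        return GRUResults(model=self, params=params, w_out=w_out,
                          b_out=float(b_out[0]), history=pd.DataFrame(rows),
                          converged_epoch=best_epoch + 1)

    def validation_mse(self, results: GRUResults, val_fraction: float = 0.25
                       ) -> float:
        """MSE of the fitted model on the chronological tail holdout,
        on the standardized scale (the GA fitness)."""
        y_std = (self.y - self._y_mean) / self._y_scale
        X_std = (None if self.exog is None
                 else (self.exog - self._x_mean) / self._x_scale)
        seqs, targets = _build_windows(y_std, X_std, self.spec.window)
        n_val = max(1, int(round(len(seqs) * val_fraction)))
        pred = self._forward_batch(results.params, results.w_out,
                                   results.b_out, seqs[-n_val:])
        return fitness(pred, targets[-n_val:])


# ---------------------------------------------------------------------------
# genetic algorithm over (feature mask, hidden size, learning rate)


@dataclass
class GAConfig:
    """Genetic-algorithm bookkeeping.  ``mutation_prob`` is the per-element
    mutation trigger and the lower acceptance bound of the position-mutation
    draw; ``unbiased_mutation`` switches the draw to plain uniform."""

    population: int = 12
    generations: int = 8
    crossover_prob: float = 0.5
    mutation_prob: float = 0.1
    elitism: int = 1
    seed: int = 0
    unbiased_mutation: bool = False
    inner_epochs: int = 30
    inner_patience: int = 5
    val_fraction: float = 0.25

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0.0 < self.mutation_prob < 1.0:
            raise ValueError("mutation_prob must lie in (0, 1)")


@dataclass
class Genome:
    """Real-coded individual: feature-inclusion genes (threshold 0.5), a
    hidden-size gene and a learning-rate gene, all on [0, 1] slots."""

    values: np.ndarray
    n_features: int
    hidden_bounds: tuple[int, int] = (4, 32)
    lr_bounds: tuple[float, float] = (1e-4, 0.1)

    @classmethod
    def random(cls, n_features: int, rng, **kw) -> "Genome":
        return cls(values=rng.random(n_features + 2), n_features=n_features,
                   **kw)

    @property
    def mask(self) -> np.ndarray:
        return self.values[:self.n_features] >= 0.5

    @property
    def hidden(self) -> int:
        lo, hi = self.hidden_bounds
        return int(round(lo + (hi - lo) * self.values[self.n_features]))

    @property
    def learning_rate(self) -> float:
        lo, hi = self.lr_bounds
        g = self.values[self.n_features + 1]
        return float(10.0 ** (np.log10(lo) + g * (np.log10(hi) - np.log10(lo))))


@dataclass
class GAResults:
    """Outcome of the GA search: the best genome, its decoded settings,
    fitness trace and final population."""

    best: Genome
    best_fitness: float
    trace: np.ndarray                 # per-generation best fitness
    population: list[Genome]
    fitnesses: np.ndarray

    def summary(self) -> str:
        return "\n".join([
            "GA-GRU optimization",
            f"  generations: {len(self.trace)}   "
            f"population: {len(self.population)}",
            f"  best validation MSE: {self.best_fitness:.5f}",
            f"  selected features: {np.flatnonzero(self.best.mask).tolist()}",
            f"  hidden units: {self.best.hidden}   "
            f"learning rate: {self.best.learning_rate:.4g}",
        ])


def ga_optimize(y, exog, spec: ForecastSpec | None = None,
                ga: GAConfig | None = None,
                hidden_bounds: tuple[int, int] = (4, 32),
                lr_bounds: tuple[float, float] = (1e-4, 0.1)) -> GAResults:
    """Search feature mask + GRU hyperparameters by GA.

    Each genome decodes to a feature subset, hidden size and learning rate;
    fitness is the validation MSE of a briefly trained GRU (chronological
    tail holdout).  Selection is inverse-fitness roulette, crossover swaps
    positions, mutation resamples selected positions, and elitism carries
    the best individuals (with cached fitness) into the next generation, so
    the best-fitness trace is monotone non-increasing.
    """
    y = np.asarray(y, dtype=float)
    exog = np.atleast_2d(np.asarray(exog, dtype=float).T).T
    spec = spec or ForecastSpec()
    ga = ga or GAConfig()
    n_features = exog.shape[1]
    rng = np.random.default_rng(ga.seed)
    kw = dict(hidden_bounds=hidden_bounds, lr_bounds=lr_bounds)

    def evaluate(genome: Genome, train_seed: int) -> float:
        if not genome.mask.any():
            return np.inf
        model = GRUForecaster(y, exog[:, genome.mask], spec=spec,
                              hidden=genome.hidden,
                              learning_rate=genome.learning_rate)
        res = model.fit(epochs=ga.inner_epochs, seed=train_seed,
                        val_fraction=ga.val_fraction,
                        patience=ga.inner_patience)
        return model.validation_mse(res, ga.val_fraction)

    pop = [Genome.random(n_features, rng, **kw) for _ in range(ga.population)]
    fits = np.array([evaluate(g, int(rng.integers(2 ** 31))) for g in pop])
    trace = []
    for gen in range(ga.generations):
        order = np.argsort(fits)
        trace.append(float(fits[order[0]]))
        elite = [Genome(pop[i].values.copy(), n_features, **kw)
                 for i in order[:ga.elitism]]
        elite_fits = fits[order[:ga.elitism]]
        children, child_fits = list(elite), list(elite_fits)
        while len(children) < ga.population:
            pa = pop[roulette_select(fits, rng)]
            pb = pop[roulette_select(fits, rng)]
            ca, cb = real_crossover(pa.values, pb.values, ga.crossover_prob,
                                    rng)
            for vals in (ca, cb):
                if len(children) >= ga.population:
                    break
                vals = position_mutate(vals, 0.0, 1.0, ga.mutation_prob, rng,
                                       per_element_prob=ga.mutation_prob,
                                       unbiased=ga.unbiased_mutation)
                child = Genome(vals, n_features, **kw)
                children.append(child)
                child_fits.append(evaluate(child,
                                           int(rng.integers(2 ** 31))))
        pop, fits = children, np.array(child_fits)
    best_i = int(np.argmin(fits))
    trace.append(float(fits[best_i]))
    return GAResults(best=pop[best_i], best_fitness=float(fits[best_i]),
                     trace=np.asarray(trace), population=pop, fitnesses=fits)
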