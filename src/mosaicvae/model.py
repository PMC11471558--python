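"""Modular product-of-experts VAE for mosaic trimodal single-cell data.

The generative model assumes each cell has a biological-state latent ``c``
and a technical-noise latent ``u`` with standard-normal priors; the batch ID
``s`` is generated from ``u`` alone (Categorical via a batch decoder), and
each measured modality ``x^m`` is generated from ``(c, u)`` through a
modality decoder — Bernoulli means for binarized ATAC, Poisson means for RNA
and ADT counts.  Inference combines one diagonal-Gaussian "expert" per
available input (batch ID, each measured modality) with the prior by a
product of experts, so one set of (M + 1) encoders serves every modality
combination.

Training minimizes a weighted negative ELBO plus two auxiliary objectives:

* a self-supervised modality-alignment penalty — the dispersion of
  reparameterized samples drawn from each single-modality posterior; and
* an information-bottleneck pair that keeps batch information out of ``c``
  and biological information out of ``u``, implemented adversarially with
  batch classifiers that are updated K times per joint update.

The public fitting surface follows the Model / Results convention:
``MosaicVAE(dataset).fit()`` returns a :class:`MosaicVAEResults` from which
embeddings, imputation, batch correction and transfer learning hang.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import gammaln, xlogy

from ._autograd import Tensor, concat
from .data import ADT, ATAC, RNA, MosaicDataset, split_train_val
from .nn import AdamW, HiddenBlock, Linear, MLP, Module

__all__ = [
    "Architecture", "LossWeights", "GaussianPosterior", "MosaicVAE",
    "MosaicVAEResults", "poe_combine", "alignment_loss", "ib_loss",
    "classifier_loss", "bernoulli_nll", "poisson_nll", "kl_diag_gaussian",
]

_LOGVAR_LO, _LOGVAR_HI = np.log(1e-4), np.log(1e4)


# ----------------------------------------------------------------- configs

@dataclass
class Architecture:
    """Network sizes.  Defaults are the full-scale settings; tests and the
    bundled synthetic benchmarks use smaller values."""

    d_c: int = 32
    d_u: int = 2
    enc_hidden: tuple[int, ...] = (1024, 128)   # first entry: per-modality input block
    dec_hidden: tuple[int, ...] = (128, 1024)   # all shared; per-modality output head
    clf_hidden: tuple[int, ...] = (128, 128)
    dropout: float = 0.2
    atac_split: bool = True        # split the ATAC input/output layers by chromosome
    scaled_rates: bool = True      # Poisson rates = softmax * observed library size

    @property
    def d_z(self) -> int:
        return self.d_c + self.d_u

    def validate(self) -> "Architecture":
        if self.d_c < 1 or self.d_u < 1:
            raise ValueError("latent sizes must be >= 1")
        if min(self.enc_hidden) < 1 or min(self.dec_hidden) < 1:
            raise ValueError("hidden sizes must be positive")
        return self


@dataclass
class LossWeights:
    alpha: float = 50.0    # modality alignment
    beta_s: float = 30.0   # technical information bottleneck
    beta_x: float = 4.0    # biological information bottleneck
    gamma: float = 1000.0  # batch-ID likelihood
    K: int = 3             # classifier updates per joint update

    def validate(self) -> "LossWeights":
        if min(self.alpha, self.beta_s, self.beta_x) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.gamma < 1 or self.K < 1:
            raise ValueError("require gamma >= 1 and K >= 1")
        return self


@dataclass
class GaussianPosterior:
    """Diagonal-Gaussian posterior over the joint latent z = (c, u)."""

    mu: np.ndarray   # rows x d_z
    nu: np.ndarray   # rows x d_z, strictly positive

    def split(self, d_c: int):
        return (self.mu[:, :d_c], self.nu[:, :d_c],
                self.mu[:, d_c:], self.nu[:, d_c:])


# ------------------------------------------------- closed-form loss pieces
# numpy reference forms; the training loop applies the same formulas on the
# autodiff tape.

def poe_combine(experts, d: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Product of diagonal-Gaussian experts with the standard-normal prior.

    ``nu = (1 + sum 1/nu_i)^-1`` and ``mu = nu * sum(mu_i / nu_i)``; with an
    empty expert list the prior (0, 1) of dimension `d` is returned.
    """
    if not experts:
        if d is None:
            raise ValueError("dimension required when no experts are given")
        return np.zeros(d), np.ones(d)
    mus = [np.asarray(m, dtype=float) for m, _ in experts]
    nus = [np.asarray(v, dtype=float) for _, v in experts]
    for v in nus:
        if (v <= 0).any():
            raise ValueError("expert variances must be strictly positive")
    prec = sum(1.0 / v for v in nus)
    nu = 1.0 / (1.0 + prec)
    mu = nu * sum(m / v for m, v in zip(mus, nus))
    return mu, nu


def alignment_loss(samples, alpha: float) -> float:
    """alpha * sum_m ||z^m - mean(z)||^2 over unimodal latent samples."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) <= 1:
        return 0.0
    zbar = np.mean(samples, axis=0)
    return float(alpha * sum(((s - zbar) ** 2).sum() for s in samples))

def bernoulli_nll(x, lam) -> np.ndarray:
    x, lam = np.asarray(x, dtype=float), np.asarray(lam, dtype=float)
    return -(xlogy(x, lam) + xlogy(1 - x, 1 - lam))


def poisson_nll(x, lam) -> np.ndarray:
    x, lam = np.asarray(x, dtype=float), np.asarray(lam, dtype=float)
    return lam - xlogy(x, lam) + gammaln(x + 1)


def kl_diag_gaussian(mu, nu) -> np.ndarray:
    """KL[N(mu, diag nu) || N(0, I)] per row."""
    mu, nu = np.asarray(mu, dtype=float), np.asarray(nu, dtype=float)
    return 0.5 * (nu + mu ** 2 - 1.0 - np.log(nu)).sum(axis=-1)


def ib_loss(log_clf_s_given_c, kl_u, log_dec_s_given_u,
            beta_s: float, beta_x: float) -> np.ndarray:
    """Information-bottleneck penalty for one posterior.

    ``+beta_s E[log p_eta(s|c)] + beta_x KL[q(u)||N(0,I)] - beta_x E[log p_theta(s|u)]``
    """
    return (beta_s * np.asarray(log_clf_s_given_c)
            + beta_x * np.asarray(kl_u)
            - beta_x * np.asarray(log_dec_s_given_u))


def classifier_loss(log_probs_joint, log_probs_per_modality) -> np.ndarray:
    """Negative log-likelihood of the true batch under every batch classifier."""
    total = -np.asarray(log_probs_joint, dtype=float)
    for lp in log_probs_per_modality:
        total = total - np.asarray(lp, dtype=float)
    return total


def _poe_t(experts: list[tuple[Tensor, Tensor]]) -> tuple[Tensor, Tensor]:
    prec = None
    wsum = None
    for mu, nu in experts:
        p = nu ** -1.0
        prec = p if prec is None else prec + p
        w = mu / nu
        wsum = w if wsum is None else wsum + w
    nu = (prec + 1.0) ** -1.0
    return wsum * nu, nu


# ------------------------------------------------------------------ networks

class _SplitLinear(Module):
    """Block-diagonal input layer: independent linear maps per chromosome block."""

    def __init__(self, block_idx: np.ndarray, d_out: int, rng):
        self.block_idx = np.asarray(block_idx)
        blocks = np.unique(self.block_idx)
        sizes = np.maximum(1, np.bincount(self.block_idx, minlength=blocks.max() + 1)
                           [blocks] * d_out // len(self.block_idx))
        self.cols = [np.flatnonzero(self.block_idx == b) for b in blocks]
        self.lins = [Linear(len(c), s, rng) for c, s in zip(self.cols, sizes)]

    def __call__(self, x: Tensor) -> Tensor:
        return concat([lin(x[:, c]) for lin, c in zip(self.lins, self.cols)], axis=-1)

    @property
    def d_out(self) -> int:
        return sum(lin.b.shape[0] for lin in self.lins)


class _InputBlock(Module):
    """Per-modality encoder front: (possibly split) linear + LayerNorm + Mish + Dropout."""

    def __init__(self, d_in: int, d_out: int, rng, dropout: float,
                 block_idx: np.ndarray | None = None):
        from .nn import LayerNorm
        if block_idx is not None:
            self.lin = _SplitLinear(block_idx, d_out, rng)
            d_out = self.lin.d_out
        else:
            self.lin = Linear(d_in, d_out, rng)
        self.norm = LayerNorm(d_out)
        self.dropout = dropout
        self.d_out = d_out

    def __call__(self, x, train=False, rng=None):
        h = self.norm(self.lin(x)).mish()
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            h = h * Tensor((rng.random(h.shape) < keep) / keep)
        return h


class Networks(Module):
    """All parameter groups of the model."""

    def __init__(self, arch: Architecture, feature_sizes: dict[str, int],
                 n_batches: int, rng: np.random.Generator,
                 atac_blocks: np.ndarray | None = None):
        arch.validate()
        self.arch = arch
        self.feature_sizes = dict(feature_sizes)
        self.n_batches = n_batches
        d_z = arch.d_z
        h_in, shared = arch.enc_hidden[0], arch.enc_hidden[1:]

        self.enc_in = {}
        for m, D in feature_sizes.items():
            blocks = atac_blocks if (m == ATAC and arch.atac_split) else None
            self.enc_in[m] = _InputBlock(D, h_in, rng, arch.dropout, blocks)
        widths = [max(b.d_out for b in self.enc_in.values()), *shared]
        self.enc_shared = [HiddenBlock(a, b, rng, arch.dropout)
                           for a, b in zip(widths[:-1], widths[1:])]
        self.enc_head = Linear(widths[-1], 2 * d_z, rng)
        # The batch-ID expert parameterizes only the technical-noise block: s
        # carries no biological information, so its expert is flat over c
        # (mean 0, near-infinite variance) and cannot leak batch identity
        # into the biological embedding through the product of experts.
        self.enc_batch = MLP(n_batches, [arch.enc_hidden[-1]], 2 * arch.d_u, rng,
                             arch.dropout)

        self.dec_shared = [HiddenBlock(a, b, rng, arch.dropout)
                           for a, b in zip([d_z, *arch.dec_hidden[:-1]], arch.dec_hidden)]
        self.dec_head = {m: Linear(arch.dec_hidden[-1], D, rng)
                         for m, D in feature_sizes.items()}
        self.dec_batch = MLP(arch.d_u, [arch.dec_hidden[0]], n_batches, rng, arch.dropout)

        self.clf_joint = MLP(arch.d_c, list(arch.clf_hidden), n_batches, rng, 0.0)
        self.clf_mod = {m: MLP(arch.d_c, list(arch.clf_hidden), n_batches, rng, 0.0)
                        for m in feature_sizes}

    # ---------------------------------------------------------- param groups
    def eta_params(self):
        out = self.clf_joint.parameters()
        for m in sorted(self.clf_mod):
            out += self.clf_mod[m].parameters()
        return out

    def batch_params(self):
        return self.enc_batch.parameters() + self.dec_batch.parameters()

    def modality_params(self):
        out = []
        for m in sorted(self.enc_in):
            out += self.enc_in[m].parameters()
        for blk in self.enc_shared:
            out += blk.parameters()
        out += self.enc_head.parameters()
        for blk in self.dec_shared:
            out += blk.parameters()
        for m in sorted(self.dec_head):
            out += self.dec_head[m].parameters()
        return out

    def theta_phi_params(self):
        return self.modality_params() + self.batch_params()

    # --------------------------------------------------------------- forward
    def _gauss_head(self, out: Tensor) -> tuple[Tensor, Tensor]:
        d_z = self.arch.d_z
        mu = out[:, :d_z]
        nu = out[:, d_z:].clamp(_LOGVAR_LO, _LOGVAR_HI).exp()
        return mu, nu

    def encode_modality(self, m: str, x, train=False, rng=None) -> tuple[Tensor, Tensor]:
        """Gaussian expert for one padded, transformed modality matrix."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        if not np.isfinite(x.data).all():
            raise ValueError(f"non-finite values in {m} encoder input")
        h = self.enc_in[m](x, train=train, rng=rng)
        for blk in self.enc_shared:
            h = blk(h, train=train, rng=rng)
        return self._gauss_head(self.enc_head(h))

    def encode_batch(self, s_onehot, train=False, rng=None) -> tuple[Tensor, Tensor]:
        s = np.asarray(s_onehot, dtype=float)
        if (s.shape[-1] != self.n_batches or not np.isin(s, (0.0, 1.0)).all()
                or not (s.sum(-1) == 1).all()):
            raise ValueError("batch IDs must be one-hot over 1..B")
        out = self.enc_batch(Tensor(s), train=train, rng=rng)
        d_u = self.arch.d_u
        mu_u = out[:, :d_u]
        nu_u = out[:, d_u:].clamp(_LOGVAR_LO, _LOGVAR_HI).exp()
        n, d_c = s.shape[0], self.arch.d_c
        mu = concat([Tensor(np.zeros((n, d_c))), mu_u], axis=-1)
        nu = concat([Tensor(np.full((n, d_c), 1e4)), nu_u], axis=-1)
        return mu, nu

    def decode(self, c: Tensor, u: Tensor, train=False, rng=None) -> dict[str, Tensor]:
        """Per-modality decoder pre-link outputs (logits) over the full unions."""
        if not (np.isfinite(c.data).all() and np.isfinite(u.data).all()):
            raise ValueError("non-finite latent values")
        h = concat([c, u], axis=-1)
        for blk in self.dec_shared:
            h = blk(h, train=train, rng=rng)
        return {m: head(h) for m, head in self.dec_head.items()}

    def decode_batch(self, u: Tensor, train=False, rng=None) -> Tensor:
        """Log-probabilities of batch IDs given u (softmax over B)."""
        logits = self.dec_batch(u, train=train, rng=rng)
        return logits - logits.logsumexp(axis=-1, keepdims=True)

    def clone(self) -> "Networks":
        blocks = None
        if ATAC in self.enc_in and isinstance(self.enc_in[ATAC].lin, _SplitLinear):
            blocks = self.enc_in[ATAC].lin.block_idx
        dup = Networks(self.arch, self.feature_sizes, self.n_batches,
                       np.random.default_rng(0), atac_blocks=blocks)
        dup.load_state_arrays([a.copy() for a in self.state_arrays()])
        return dup


def modality_means(networks: Networks, logits: dict[str, Tensor] | dict[str, np.ndarray],
                   libraries: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
    """Map decoder outputs to modality means over full unions (numpy, mean mode)."""
    out = {}
    for m, lg in logits.items():
        arr = lg.data if isinstance(lg, Tensor) else np.asarray(lg, dtype=float)
        if m == ATAC:
            out[m] = 1.0 / (1.0 + np.exp(-arr))
        elif networks.arch.scaled_rates:
            p = np.exp(arr - arr.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            lib = libraries[m] if libraries else np.ones((arr.shape[0], 1))
            out[m] = p * np.reshape(lib, (-1, 1))
        else:
            out[m] = np.logaddexp(0.0, arr)
    return out


# --------------------------------------------------------------- training data

class _GroupData:
    """Per-experimental-batch dense views used by the training loop."""

    def __init__(self, record, spaces, n_batches: int, arch: Architecture):
        self.batch_id = record.batch_id
        self.modalities = record.measured_modalities
        self.n = record.n_cells
        self.x_raw, self.x_enc, self.obs_idx, self.lib, self.log_fact = {}, {}, {}, {}, {}
        for m in self.modalities:
            X = np.asarray(record.counts[m].todense(), dtype=float)
            mask = record.feature_mask[m].astype(bool)
            self.obs_idx[m] = np.flatnonzero(mask)
            self.x_raw[m] = X
            enc = X if m == ATAC else np.log1p(X)
            self.x_enc[m] = enc * mask  # masked-out columns never reach the encoder
            self.lib[m] = X[:, mask].sum(axis=1, keepdims=True)
            if m != ATAC:
                self.log_fact[m] = gammaln(X[:, mask] + 1.0).sum(axis=1)
        self.s_onehot = np.zeros((self.n, n_batches))
        self.s_onehot[:, record.batch_id - 1] = 1.0
        self.s_idx = np.full(self.n, record.batch_id - 1)

    def rows(self, idx: np.ndarray) -> "_GroupData":
        sub = object.__new__(_GroupData)
        sub.batch_id, sub.modalities, sub.n = self.batch_id, self.modalities, len(idx)
        sub.obs_idx = self.obs_idx
        sub.x_raw = {m: X[idx] for m, X in self.x_raw.items()}
        sub.x_enc = {m: X[idx] for m, X in self.x_enc.items()}
        sub.lib = {m: v[idx] for m, v in self.lib.items()}
        sub.log_fact = {m: v[idx] for m, v in self.log_fact.items()}
        sub.s_onehot = self.s_onehot[idx]
        sub.s_idx = self.s_idx[idx]
        return sub


def _pick(log_probs: Tensor, s_idx: np.ndarray) -> Tensor:
    return log_probs[np.arange(len(s_idx)), s_idx]


def _kl_t(mu: Tensor, nu: Tensor) -> Tensor:
    return ((nu + mu * mu - 1.0 - nu.log()) * 0.5).sum(axis=-1)


class _Forward:
    """One tape through encoders + PoE + sampling for a group of cells."""

    def __init__(self, networks: Networks, g: _GroupData, rng, train: bool):
        arch = networks.arch
        self.g, self.networks = g, networks
        self.experts = {}
        self.experts["batch"] = networks.encode_batch(g.s_onehot, train=train, rng=rng)
        for m in g.modalities:
            self.experts[m] = networks.encode_modality(m, g.x_enc[m], train=train, rng=rng)
        self.joint = _poe_t([self.experts["batch"],
                             *[self.experts[m] for m in g.modalities]])
        self.unimodal = {m: _poe_t([self.experts["batch"], self.experts[m]])
                         for m in g.modalities}
        d_z = arch.d_z
        eps = rng.standard_normal((g.n, d_z))
        mu, nu = self.joint
        self.z = mu + nu.sqrt() * Tensor(eps)
        self.z_m = {}
        for m in g.modalities:
            mu_m, nu_m = self.unimodal[m]
            self.z_m[m] = mu_m + nu_m.sqrt() * Tensor(rng.standard_normal((g.n, d_z)))

    def split(self, z: Tensor) -> tuple[Tensor, Tensor]:
        d_c = self.networks.arch.d_c
        return z[:, :d_c], z[:, d_c:]


def _recon_nll(networks: Networks, g: _GroupData, logits: dict[str, Tensor]) -> Tensor:
    """Masked reconstruction NLL per cell, summed over measured modalities."""
    total = None
    for m in g.modalities:
        obs = g.obs_idx[m]
        lg = logits[m][:, obs]
        x = g.x_raw[m][:, obs]
        if m == ATAC:
            nll = (lg.softplus() - lg * Tensor(x)).sum(axis=-1)
        else:
            if networks.arch.scaled_rates:
                log_rate = lg - lg.logsumexp(axis=-1, keepdims=True)
                log_lam = log_rate + Tensor(np.log(np.maximum(g.lib[m], 1.0)))
            else:
                log_lam = lg.softplus().clamp(1e-12, np.inf).log()
            nll = (log_lam.exp() - Tensor(x) * log_lam).sum(axis=-1) + Tensor(g.log_fact[m])
        total = nll if total is None else total + nll
    return total


def _group_joint_loss(networks: Networks, fwd: _Forward, weights: LossWeights,
                      rng, train: bool) -> tuple[Tensor, dict[str, float]]:
    """Mean-per-cell ELBO + alignment + IB losses for one group (sum over cells)."""
    g = fwd.g
    c, u = fwd.split(fwd.z)
    logits = networks.decode(c, u, train=train, rng=rng)
    log_ps = _pick(networks.decode_batch(u, train=train, rng=rng), g.s_idx)
    recon = _recon_nll(networks, g, logits)
    mu, nu = fwd.joint
    kl = _kl_t(mu, nu)
    elbo_loss_vec = recon - weights.gamma * log_ps + kl

    # modality alignment on unimodal samples
    if len(g.modalities) > 1:
        zbar = None
        for m in g.modalities:
            zbar = fwd.z_m[m] if zbar is None else zbar + fwd.z_m[m]
        zbar = zbar * (1.0 / len(g.modalities))
        align = None
        for m in g.modalities:
            d = fwd.z_m[m] - zbar
            term = (d * d).sum(axis=-1)
            align = term if align is None else align + term
        align_vec = weights.alpha * align
    else:
        align_vec = Tensor(np.zeros(g.n))

    # information bottleneck: joint posterior term + one term per modality
    d_c = networks.arch.d_c
    ib_vec = None
    posteriors = [(fwd.joint, fwd.z, networks.clf_joint)]
    posteriors += [((fwd.unimodal[m]), fwd.z_m[m], networks.clf_mod[m])
                   for m in g.modalities]
    for (mu_p, nu_p), z_p, clf in posteriors:
        c_p, u_p = fwd.split(z_p)
        lp = clf(c_p)
        log_clf = _pick(lp - lp.logsumexp(axis=-1, keepdims=True), g.s_idx)
        kl_u = _kl_t(mu_p[:, d_c:], nu_p[:, d_c:])
        log_dec = _pick(networks.decode_batch(u_p, train=train, rng=rng), g.s_idx)
        term = weights.beta_s * log_clf + weights.beta_x * kl_u - weights.beta_x * log_dec
        ib_vec = term if ib_vec is None else ib_vec + term

    total = (elbo_loss_vec + align_vec + ib_vec).sum()
    parts = {"elbo": float(elbo_loss_vec.data.sum()),
             "align": float(align_vec.data.sum()),
             "ib": float(ib_vec.data.sum())}
    return total, parts


def _group_classifier_loss(networks: Networks, fwd: _Forward) -> Tensor:
    """Batch-classifier NLL on detached latent samples, summed over cells."""
    g = fwd.g
    d_c = networks.arch.d_c
    c = fwd.z.detach()[:, :d_c]
    logp = networks.clf_joint(c)
    loss = -_pick(logp - logp.logsumexp(axis=-1, keepdims=True), g.s_idx)
    for m in g.modalities:
        c_m = fwd.z_m[m].detach()[:, :d_c]
        lp = networks.clf_mod[m](c_m)
        loss = loss - _pick(lp - lp.logsumexp(axis=-1, keepdims=True), g.s_idx)
    return loss.sum()


# ---------------------------------------------------------------- the model

class MosaicVAE:
    """Mosaic-integration model bound to a dataset.

    Parameters
    ----------
    dataset
        Validated :class:`~mosaicvae.data.MosaicDataset`.
    architecture, loss_weights
        Network sizes and objective weights; defaults follow the standard
        full-scale configuration.
    """

    def __init__(self, dataset: MosaicDataset,
                 architecture: Architecture | None = None,
                 loss_weights: LossWeights | None = None):
        self.dataset = dataset.validate()
        self.architecture = (architecture or Architecture()).validate()
        self.loss_weights = (loss_weights or LossWeights()).validate()

    def fit(self, epochs: int = 2000, lr: float = 1e-4, batch_size: int = 256,
            val_ratio: float = 0.05, patience: int = 10, min_delta: float = 0.0,
            seed: int = 0, verbose: bool = False,
            networks: Networks | None = None,
            finetune_params: str = "all",
            sampler=None) -> "MosaicVAEResults":
        """Run the alternating training algorithm.

        Each iteration performs K gradient steps on the batch classifiers
        (encoders frozen via detached samples) followed by one step on the
        encoder/decoder parameters (classifiers held fixed), both with AdamW.
        Early stopping watches the batch-stratified validation loss.
        """
        ss = np.random.SeedSequence(seed)
        init_rng, samp_rng, shuf_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
        ds = self.dataset
        arch, weights = self.architecture, self.loss_weights

        if networks is None:
            spaces = ds.feature_spaces
            blocks = (spaces[ATAC].atac_chrom_blocks if ATAC in spaces else None)
            networks = Networks(arch, {m: spaces[m].size for m in ds.modalities},
                                ds.B, init_rng, atac_blocks=blocks)

        groups = [_GroupData(b, ds.feature_spaces, ds.B, arch) for b in ds.batches]
        offsets = np.cumsum([0] + [g.n for g in groups])
        batch_of_cell = np.concatenate([np.full(g.n, i) for i, g in enumerate(groups)])
        local_idx = np.concatenate([np.arange(g.n) for g in groups])

        train_idx, val_idx = split_train_val(ds, 1.0 - val_ratio, seed=seed)

        if finetune_params == "all":
            joint_params = networks.theta_phi_params()
        elif finetune_params == "modality":
            joint_params = networks.modality_params() + networks.batch_params()
        else:
            raise ValueError(f"unknown finetune_params {finetune_params!r}")
        opt_joint = AdamW(joint_params, lr=lr)
        opt_clf = AdamW(networks.eta_params(), lr=lr)

        log: list[dict] = []
        best_val, best_state, best_epoch = np.inf, None, -1
        n_clf_updates = n_joint_updates = 0

        def eval_loss(idx: np.ndarray, rng) -> float:
            if len(idx) == 0:
                return np.nan
            total = 0.0
            for gi in np.unique(batch_of_cell[idx]):
                rows = local_idx[idx[batch_of_cell[idx] == gi]]
                sub = groups[gi].rows(rows)
                fwd = _Forward(networks, sub, rng, train=False)
                loss, _ = _group_joint_loss(networks, fwd, weights, rng, train=False)
                total += float(loss.data)
            return total / len(idx)

        for epoch in range(epochs):
            if sampler is None:
                order = shuf_rng.permutation(train_idx)
                minibatches = [order[i:i + batch_size]
                               for i in range(0, len(order), batch_size)]
            else:
                minibatches = sampler(shuf_rng, batch_size)
            epoch_loss, n_seen = 0.0, 0
            for mb in minibatches:
                if len(mb) == 0:
                    continue
                subs = []
                for gi in np.unique(batch_of_cell[mb]):
                    rows = local_idx[mb[batch_of_cell[mb] == gi]]
                    subs.append(groups[gi].rows(rows))
                fwds = [_Forward(networks, sub, samp_rng, train=True) for sub in subs]
                for _ in range(weights.K):
                    opt_clf.zero_grad()
                    closs = None
                    for fwd in fwds:
                        part = _group_classifier_loss(networks, fwd)
                        closs = part if closs is None else closs + part
                    (closs * (1.0 / len(mb))).backward()
                    opt_clf.step()
                    n_clf_updates += 1
                opt_joint.zero_grad()
                jloss = None
                for fwd in fwds:
                    part, _ = _group_joint_loss(networks, fwd, weights, samp_rng,
                                                train=True)
                    jloss = part if jloss is None else jloss + part
                jval = float(jloss.data) / len(mb)
                if not np.isfinite(jval):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}, "
                        f"iteration {n_joint_updates}")
                (jloss * (1.0 / len(mb))).backward()
                opt_joint.step()
                n_joint_updates += 1
                epoch_loss += jval * len(mb)
                n_seen += len(mb)

            val_rng = np.random.default_rng(np.random.SeedSequence([seed, epoch]))
            val_loss = eval_loss(val_idx, val_rng)
            log.append({"epoch": epoch, "train_loss": epoch_loss / max(n_seen, 1),
                        "val_loss": val_loss,
                        "classifier_updates": n_clf_updates,
                        "joint_updates": n_joint_updates})
            if verbose:
                print(f"epoch {epoch}: train {log[-1]['train_loss']:.3f} "
                      f"val {val_loss:.3f}")
            monitor = val_loss if np.isfinite(val_loss) else log[-1]["train_loss"]
            if monitor < best_val - min_delta:
                best_val, best_epoch = monitor, epoch
                best_state = [a.copy() for a in networks.state_arrays()]
            elif epoch - best_epoch >= patience:
                break

        if best_state is not None:
            networks.load_state_arrays(best_state)
        return MosaicVAEResults(self, networks, log)


class MosaicVAEResults:
    """Fitted model: parameters, training log, and the downstream task heads."""

    def __init__(self, model: MosaicVAE, networks: Networks, training_log: list[dict]):
        self.model = model
        self.networks = networks
        self.training_log = training_log

    # task heads are implemented in mosaicvae.tasks and bound here for the
    # Model/Results-style surface
    def infer_latent(self, dataset: MosaicDataset | None = None):
        from .tasks import infer_latent
        return infer_latent(self, dataset or self.model.dataset)

    def impute(self, latent=None, mode: str = "mean", seed: int = 0):
        from .tasks import impute
        return impute(self, latent or self.infer_latent(), mode=mode, seed=seed)

    def batch_correct(self, latent=None):
        from .tasks import batch_correct
        return batch_correct(self, latent or self.infer_latent())

    def summary(self) -> str:
        arch, w = self.model.architecture, self.model.loss_weights
        last = self.training_log[-1] if self.training_log else {}
        lines = [
            "Mosaic product-of-experts VAE",
            "=" * 46,
            f"cells: {self.model.dataset.N}   batches: {self.model.dataset.B}   "
            f"modalities: {', '.join(self.model.dataset.modalities)}",
            f"latents: d_c={arch.d_c}  d_u={arch.d_u}   "
            f"hidden: enc {arch.enc_hidden} / dec {arch.dec_hidden}",
            f"weights: alpha={w.alpha} beta_s={w.beta_s} beta_x={w.beta_x} "
            f"gamma={w.gamma} K={w.K}",
            f"epochs run: {len(self.training_log)}   "
            f"final train loss: {last.get('train_loss', float('nan')):.4f}   "
            f"final val loss: {last.get('val_loss', float('nan')):.4f}",
            f"classifier/joint updates: {last.get('classifier_updates', 0)}/"
            f"{last.get('joint_updates', 0)}",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "format": "mosaicvae-checkpoint-v1",
            "architecture": asdict(self.model.architecture),
            "loss_weights": asdict(self.model.loss_weights),
            "feature_sizes": self.networks.feature_sizes,
            "n_batches": self.networks.n_batches,
            "feature_names": {m: s.names for m, s in
                              self.model.dataset.feature_spaces.items()},
            "training_log": self.training_log,
        }
        arrays = {f"param_{i}": a for i, a in enumerate(self.networks.state_arrays())}
        blocks = None
        if ATAC in self.networks.enc_in and isinstance(self.networks.enc_in[ATAC].lin,
                                                       _SplitLinear):
            blocks = self.networks.enc_in[ATAC].lin.block_idx
        np.savez_compressed(path, meta=json.dumps(meta),
                            atac_blocks=blocks if blocks is not None else np.array([]),
                            **arrays)

    @classmethod
    def load(cls, path, dataset: MosaicDataset) -> "MosaicVAEResults":
        with np.load(Path(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            if meta.get("format") != "mosaicvae-checkpoint-v1":
                raise ValueError("unrecognized checkpoint format")
            arch = Architecture(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in meta["architecture"].items()})
            weights = LossWeights(**meta["loss_weights"])
            blocks = archive["atac_blocks"]
            blocks = blocks if blocks.size else None
            networks = Networks(arch, meta["feature_sizes"], meta["n_batches"],
                                np.random.default_rng(0), atac_blocks=blocks)
            n_params = len(networks.parameters())
            networks.load_state_arrays([archive[f"param_{i}"] for i in range(n_params)])
        model = MosaicVAE(dataset, arch, weights)
        return cls(model, networks, meta["training_log"])
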