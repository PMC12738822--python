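"""Dual-pooling gated channel attention (DCPGAttention).

Each channel of a feature map is pooled to its spatial mean and standard
deviation, the two statistics are contracted to a scalar by learnable
per-channel weights, the per-channel scalars are L2-normalised across
channels (scaled by sqrt(C) to keep magnitudes stable), and the channel is
finally rescaled by the gate ``1 + tanh(gamma * s_hat + beta)``.

The gate multiplier is confined to the open interval (0, 2), and with the
default initialisation (``gamma = beta = 0``) the module is an exact
identity, so it can be inserted into an existing network without
perturbing it.  A module on ``C`` channels carries exactly ``4 C`` learnable
scalars (mean weight, std weight, gate weight, gate bias per channel), or
``3 C`` with ``shared_alpha``.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, astensor
from .nn import Module, parameter

__all__ = ["DCPGAttention", "dcpg_forward"]


class DCPGAttention(Module):
    """Channel attention via mean/std pooling, embedding, L2 norm and tanh gate.

    Parameters
    ----------
    channels:
        Number of input channels ``C``.
    xi:
        Small stability constant added in the embedding and the normaliser.
    c_scale:
        Scale applied after L2 normalisation; defaults to ``sqrt(C)``.
    shared_alpha:
        If true, a single per-channel weight multiplies ``mu + sigma``
        instead of the separate (mean, std) pair.
    """

    def __init__(self, channels: int, xi: float = 1e-5, c_scale: float | None = None,
                 shared_alpha: bool = False):
        super().__init__()
        self.channels = channels
        self.xi = float(xi)
        if xi <= 0:
            raise ValueError("xi must be > 0")
        self.c_scale = float(c_scale) if c_scale is not None else math.sqrt(channels)
        self.shared_alpha = shared_alpha
        if shared_alpha:
            self.alpha = parameter((channels,), "ones")
        else:
            self.alpha_mu = parameter((channels,), "ones")
            self.alpha_sigma = parameter((channels,), "ones")
        self.gamma = parameter((channels,), "zeros")
        self.beta = parameter((channels,), "zeros")

    # -- the four stages ------------------------------------------------------
    def channel_stats(self, x):
        """Per-(batch, channel) spatial mean and population std of `x`."""
        x = astensor(x)
        mu = x.mean(axis=(2, 3))
        var = ((x - mu.reshape(*mu.shape, 1, 1)) ** 2).mean(axis=(2, 3))
        sigma = (var + 1e-12).sqrt()
        return mu, sigma

    def embed(self, mu, sigma):
        """Contract the (mean, std) pair to one scalar per (batch, channel)."""
        mu, sigma = astensor(mu), astensor(sigma)
        if self.shared_alpha:
            return self.alpha.reshape(1, -1) * (mu + sigma + 2 * self.xi)
        return (self.alpha_mu.reshape(1, -1) * (mu + self.xi)
                + self.alpha_sigma.reshape(1, -1) * (sigma + self.xi))

    def channel_normalize(self, s):
        """L2-normalise the embedding across channels, scaled by ``c_scale``."""
        s = astensor(s)
        norm = ((s ** 2).sum(axis=1, keepdims=True) + self.xi).sqrt()
        return s * (self.c_scale / 1.0) / norm

    def gate(self, x, s_hat):
        """Rescale each channel by ``1 + tanh(gamma * s_hat + beta)``."""
        x, s_hat = astensor(x), astensor(s_hat)
        mult = 1.0 + (self.gamma.reshape(1, -1) * s_hat + self.beta.reshape(1, -1)).tanh()
        n, c = mult.shape
        return x * mult.reshape(n, c, 1, 1)

    def forward(self, x):
        x = astensor(x)
        if x.ndim != 4:
            raise ValueError("expected a rank-4 (n, c, h, w) feature tensor")
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        mu, sigma = self.channel_stats(x)
        s = self.embed(mu, sigma)
        s_hat = self.channel_normalize(s)
        return self.gate(x, s_hat)


def dcpg_forward(x, module: DCPGAttention):
    """Functional alias for ``module(x)``."""
    return module(x)
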