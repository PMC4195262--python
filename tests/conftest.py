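"""Shared fixtures and the independent brute-force fusion oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import icextract as ic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


SMALL_AXES = dict(
    skull_axes=(13.0, 12.0, 11.5),
    ic_axes=(11.5, 10.5, 10.0),
    gm_axes=(10.0, 9.0, 8.5),
    wm_axes=(7.5, 6.5, 6.0),
    ventricle_axes=(2.5, 2.0, 1.5),
)


def small_spec(**kw) -> ic.PhantomSpec:
    """32^3 phantom spec: same anatomy at half scale, cheap to generate."""
    base = dict(shape=(32, 32, 32), noise_sd=5.0, deformation_amplitude=1.0,
                seed=0, **SMALL_AXES)
    base.update(kw)
    return ic.PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_library() -> ic.TemplateLibrary:
    """Five perturbed 32^3 phantoms sharing one grid."""
    return ic.make_library(small_spec(seed=11), 5, intensity_jitter_sd=3.0)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Undeformed noiseless 64^3 phantom with its mask and labels."""
    spec = ic.PhantomSpec(noise_sd=0.0, deformation_amplitude=0.0, seed=0)
    vol, msk, labels = ic.make_phantom(spec)
    return spec, vol, msk, labels


def naive_voxelwise_fusion(img, tmpls, labs, roi, patch_radius, search_radius,
                           lambda_h, epsilon_h, sigma_d, ss_threshold,
                           voxel_size=(1.0, 1.0, 1.0)):
    """Brute-force triple-loop weighted label fusion with the bilateral
    weight and adaptive bandwidth, written independently of the package's
    compiled kernel.  Returns (votes, mass, processed, fallback)."""
    X, Y, Z = img.shape
    N = tmpls.shape[0]
    pr, sr = patch_radius, search_radius
    votes = np.zeros(img.shape)
    mass = np.zeros(img.shape)
    proc = np.zeros(img.shape, np.uint8)
    fb = np.zeros(img.shape, np.uint8)
    for cx in range(X):
        for cy in range(Y):
            for cz in range(Z):
                if not roi[cx, cy, cz]:
                    continue
                lx, ux = min(pr, cx), min(pr, X - 1 - cx)
                ly, uy = min(pr, cy), min(pr, Y - 1 - cy)
                lz, uz = min(pr, cz), min(pr, Z - 1 - cz)
                tgt = img[cx - lx:cx + ux + 1, cy - ly:cy + uy + 1,
                          cz - lz:cz + uz + 1].ravel()
                cands = []
                for s in range(N):
                    for jx in range(max(cx - sr, lx), min(cx + sr, X - 1 - ux) + 1):
                        for jy in range(max(cy - sr, ly),
                                        min(cy + sr, Y - 1 - uy) + 1):
                            for jz in range(max(cz - sr, lz),
                                            min(cz + sr, Z - 1 - uz) + 1):
                                p = tmpls[s, jx - lx:jx + ux + 1,
                                          jy - ly:jy + uy + 1,
                                          jz - lz:jz + uz + 1].ravel()
                                d2 = float(np.sum((tgt - p) ** 2)) / tgt.size
                                cands.append((s, jx, jy, jz, p, d2))
                h = lambda_h * min(c[5] for c in cands) + epsilon_h
                tm, ts = tgt.mean(), tgt.std()
                num = den = 0.0
                labsum = 0
                for s, jx, jy, jz, p, d2 in cands:
                    pm, ps = p.mean(), p.std()
                    if tm == 0 and pm == 0:
                        mu = 1.0
                    elif tm == 0 or pm == 0:
                        mu = 0.0
                    else:
                        mu = 2 * tm * pm / (tm * tm + pm * pm)
                    if ts == 0 and ps == 0:
                        sd = 1.0
                    elif ts == 0 or ps == 0:
                        sd = 0.0
                    else:
                        sd = 2 * ts * ps / (ts * ts + ps * ps)
                    labsum += int(labs[s, jx, jy, jz])
                    if mu * sd < ss_threshold:
                        continue
                    spatial = math.sqrt(((jx - cx) * voxel_size[0]) ** 2
                                        + ((jy - cy) * voxel_size[1]) ** 2
                                        + ((jz - cz) * voxel_size[2]) ** 2)
                    w = math.exp(-(spatial / sigma_d + d2 / h))
                    num += w * labs[s, jx, jy, jz]
                    den += w
                if den > 0:
                    votes[cx, cy, cz] = num / den
                    mass[cx, cy, cz] = den
                    proc[cx, cy, cz] = 1
                else:
                    votes[cx, cy, cz] = 1 if 2 * labsum > len(cands) else 0
                    proc[cx, cy, cz] = 1
                    fb[cx, cy, cz] = 1
    return votes, mass, proc, fb


@pytest.fixture(scope="session")
def random_fusion_instance():
    """Random 12^3 subject + 3 noisy templates with random labels, the
    standard small instance for oracle comparisons."""
    rng = np.random.default_rng(7)
    img = rng.uniform(0, 300, (12, 12, 12))
    tmpls = np.stack([img + rng.normal(0, 20, img.shape) for _ in range(3)])
    labs = (rng.uniform(size=(3, 12, 12, 12)) < 0.5).astype(np.uint8)
    subject = ic.IntensityVolume(img)
    library = ic.TemplateLibrary(
        [(ic.IntensityVolume(tmpls[s]), ic.BinaryMask(labs[s])) for s in range(3)]
    )
    roi = ic.BinaryMask(np.ones((12, 12, 12), np.uint8))
    return subject, library, roi, img, tmpls, labs
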