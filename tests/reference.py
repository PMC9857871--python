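"""Naive loop-based reference implementations used as independent oracles.

Deliberately written with explicit Python loops and ``math`` only, so they
share no code path with the vectorized implementations they check.
"""

import math


def _prob(s, floor=None):
    total = sum(s)
    p = [x / total for x in s]
    if floor is not None:
        p = [max(x, floor) for x in p]
        total = sum(p)
        p = [x / total for x in p]
    return p


def sam_ref(a, b):
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return math.acos(max(-1.0, min(1.0, dot / (na * nb))))


def sid_ref(a, b):
    p = _prob(a, floor=1e-12)
    q = _prob(b, floor=1e-12)
    kl_pq = sum(pi * math.log(pi / qi) for pi, qi in zip(p, q))
    kl_qp = sum(qi * math.log(qi / pi) for pi, qi in zip(p, q))
    return kl_pq + kl_qp


def pearson_ref(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def sca_ref(a, b):
    sigma = pearson_ref(a, b)
    return math.acos(max(-1.0, min(1.0, (sigma + 1.0) / 2.0)))


def bc_ref(a, b):
    p = _prob(a)
    q = _prob(b)
    return min(1.0, sum(math.sqrt(pi * qi) for pi, qi in zip(p, q)))


def jm_ref(a, b):
    return 2.0 * (1.0 - bc_ref(a, b))


def _tan_ref(angle):
    return math.tan(min(angle, math.pi / 2 - 1e-9))


def sid_tan_sam_ref(a, b):
    return sid_ref(a, b) * _tan_ref(sam_ref(a, b))


def sid_tan_sca_ref(a, b):
    return sid_ref(a, b) * _tan_ref(sca_ref(a, b))


def sid_jm_tan_sam_ref(a, b):
    return sid_ref(a, b) * jm_ref(a, b) * _tan_ref(sam_ref(a, b))


def sid_jm_tan_sca_ref(a, b):
    return sid_ref(a, b) * jm_ref(a, b) * _tan_ref(sca_ref(a, b))


REFERENCES = {
    "SAM": sam_ref,
    "SID": sid_ref,
    "SCA": sca_ref,
    "JM": jm_ref,
    "SID-TAN(SAM)": sid_tan_sam_ref,
    "SID-TAN(SCA)": sid_tan_sca_ref,
    "SID-JM-TAN(SAM)": sid_jm_tan_sam_ref,
    "SID-JM-TAN(SCA)": sid_jm_tan_sca_ref,
}


def entropy_bits_ref(p):
    return -sum(x * math.log2(x) for x in p if x > 0)
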