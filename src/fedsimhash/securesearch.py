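"""Encrypted hamming-distance protocol between a querier and a responder.

The querier encrypts each bit of its +-1 hash code under an additively
homomorphic (Paillier) public key and ships only ciphertexts. The
responder — holding the public key only — computes the encrypted inner
product ``Enc(sum_t u_t v_t)`` by raising each ciphertext to its own +-1
bit (ciphertext exponentiation by a plaintext scalar) and multiplying the
results, then returns that single ciphertext. The querier decrypts and
converts: ``d_H = (b - <u, v>) / 2``. The responder never decrypts, never
sees plaintext bits, and answers only with one value per comparison — the
distance and nothing else.

The Paillier scheme here is self-contained: modulus n = p*q for primes of
half the key length, generator g = n + 1, Enc(m) = (1 + m n) r^n mod n^2,
Dec via the Carmichael function. Messages are signed integers in
(-n/2, n/2]. Keys of 2048 bits are standard practice; the configurable
floor is 128 bits, far below it, and short keys should only ever be used
to speed up tests.
"""

from __future__ import annotations

import hashlib
import math
import random
from dataclasses import dataclass

import numpy as np
from sympy import isprime

from fedsimhash.errors import ConfigurationError, FormatError, IntegrityError, ProtocolError

MIN_KEY_BITS = 128
DEFAULT_KEY_BITS = 2048


def _random_prime(bits: int, rng: random.Random) -> int:
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        if isprime(cand):
            return cand


@dataclass(frozen=True)
class PaillierPublicKey:
    """Encryption key: supports Enc, ciphertext addition, scalar multiply."""

    n: int

    @property
    def nsq(self) -> int:
        return self.n * self.n

    @property
    def fingerprint(self) -> str:
        return hashlib.sha256(hex(self.n).encode()).hexdigest()[:16]

    def _encode(self, m: int) -> int:
        return m % self.n

    def encrypt(self, m: int, rng: random.Random | None = None) -> int:
        """Enc(m) = (1 + m n) r^n mod n^2 with fresh randomness r."""
        rng = rng or random.SystemRandom()
        m = self._encode(int(m))
        while True:
            r = rng.randrange(1, self.n)
            if math.gcd(r, self.n) == 1:
                break
        return (1 + m * self.n) * pow(r, self.n, self.nsq) % self.nsq

    def add(self, c1: int, c2: int) -> int:
        """Homomorphic addition: Dec(add(Enc(a), Enc(b))) = a + b."""
        return c1 * c2 % self.nsq

    def mul_scalar(self, c: int, k: int) -> int:
        """Homomorphic plaintext-scalar multiply: Dec(mul(Enc(a), k)) = a k."""
        k = int(k) % self.n
        return pow(c, k, self.nsq)


@dataclass(frozen=True)
class PaillierPrivateKey:
    """Decryption key (Carmichael lambda and its inverse mod n)."""

    public: PaillierPublicKey
    lam: int
    mu: int

    def decrypt(self, c: int) -> int:
        n, nsq = self.public.n, self.public.nsq
        x = pow(int(c), self.lam, nsq)
        m = (x - 1) // n * self.mu % n
        # map back to signed representatives
        return m - n if m > n // 2 else m


@dataclass(frozen=True)
class KeyPair:
    public: PaillierPublicKey
    private: PaillierPrivateKey
    key_bits: int


def keygen(bits: int = DEFAULT_KEY_BITS, seed: int | None = None) -> KeyPair:
    """Generate a Paillier key pair with an n-modulus of ``bits`` bits.

    ``seed`` makes prime selection reproducible (tests); production keys
    should leave it unset so system randomness is used.
    """
    if bits < MIN_KEY_BITS:
        raise ConfigurationError(f"key length {bits} below the {MIN_KEY_BITS}-bit floor")
    rng = random.Random(seed) if seed is not None else random.SystemRandom()
    half = bits // 2
    while True:
        p = _random_prime(half, rng)
        q = _random_prime(bits - half, rng)
        if p != q:
            break
    n = p * q
    lam = math.lcm(p - 1, q - 1)
    mu = pow(lam, -1, n)
    pub = PaillierPublicKey(n)
    return KeyPair(public=pub, private=PaillierPrivateKey(pub, lam, mu), key_bits=bits)


@dataclass(frozen=True)
class EncryptedCodeVector:
    """One ciphertext per bit of a +-1 hash code; no plaintext retained."""

    ciphertexts: tuple[int, ...]
    key_fingerprint: str
    b: int

    def __post_init__(self):
        if len(self.ciphertexts) != self.b:
            raise FormatError(f"expected {self.b} ciphertexts, got {len(self.ciphertexts)}")


def encrypt_code(
    code, pub: PaillierPublicKey, rng: random.Random | None = None
) -> EncryptedCodeVector:
    """Encrypt a +-1 code bitwise under the public key."""
    code = np.asarray(code).ravel()
    if code.size == 0 or not np.all(np.isin(code, (-1, 1))):
        raise FormatError("hash codes must be non-empty with entries in {-1, +1}")
    cts = tuple(pub.encrypt(int(bit), rng) for bit in code)
    return EncryptedCodeVector(ciphertexts=cts, key_fingerprint=pub.fingerprint, b=code.size)


class Responder:
    """The answering site: constructed from the public key only.

    Holding no private key, it can compute over ciphertexts but can never
    decrypt — the role separation of the protocol is enforced by
    construction.
    """

    def __init__(self, pub: PaillierPublicKey):
        self.pub = pub

    def respond_distance(self, enc_query: EncryptedCodeVector, local_code) -> int:
        """Encrypted inner product of the query with a local +-1 code.

        Each ciphertext Enc(u_t) is raised to the local bit v_t and the
        results multiplied: the product decrypts to sum_t u_t v_t. One
        ciphertext is returned per comparison — never per-bit results.
        """
        if enc_query.key_fingerprint != self.pub.fingerprint:
            raise ProtocolError("query encrypted under a different public key")
        local_code = np.asarray(local_code).ravel()
        if not np.all(np.isin(local_code, (-1, 1))):
            raise FormatError("local code entries must be +-1")
        if local_code.size != enc_query.b:
            raise ProtocolError(
                f"code length mismatch: query b={enc_query.b}, local {local_code.size}"
            )
        acc = self.pub.encrypt(0)
        for ct, v in zip(enc_query.ciphertexts, local_code):
            acc = self.pub.add(acc, self.pub.mul_scalar(ct, int(v)))
        return acc


def respond_distance(enc_query: EncryptedCodeVector, local_code, pub: PaillierPublicKey) -> int:
    """Functional form of :meth:`Responder.respond_distance`."""
    return Responder(pub).respond_distance(enc_query, local_code)


def recover_hamming(response: int, priv: PaillierPrivateKey, b: int) -> int:
    """Decrypt the responder's ciphertext and convert to a hamming distance.

    For +-1 codes the inner product s satisfies d_H = (b - s) / 2; the
    decrypted value must lie in [-b, b] with the parity of b, otherwise
    the response is malformed.
    """
    inner = priv.decrypt(response)
    if not (-b <= inner <= b) or (b - inner) % 2 != 0:
        raise IntegrityError(f"decrypted inner product {inner} invalid for b={b}")
    return (b - inner) // 2
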