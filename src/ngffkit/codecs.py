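"""Per-chunk compression codecs.

A codec turns the raw row-major bytes of one chunk into the stored object
and back. The registry is pluggable so that metadata naming codecs this
package does not ship (blosc, zstd, ...) can still be parsed; attempting to
*decode* with an unregistered codec raises :class:`UnknownCodecError`.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Tuple


class UnknownCodecError(KeyError):
    """A codec id with no registered implementation."""


@dataclass(frozen=True)
class CodecSpec:
    """Identifier plus parameters of a per-chunk compressor.

    ``id`` is the wire name recorded in array metadata (e.g. ``"zlib"``);
    ``params`` holds codec options such as ``{"level": 5}``.
    """

    id: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("codec id must be non-empty")
        if any(not isinstance(k, str) for k in self.params):
            raise ValueError("codec parameter keys must be strings")

    def to_doc(self) -> Dict[str, object]:
        doc: Dict[str, object] = {"id": self.id}
        doc.update(self.params)
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping[str, object]) -> "CodecSpec":
        if "id" not in doc:
            raise ValueError("compressor document lacks an 'id'")
        params = {k: v for k, v in doc.items() if k != "id"}
        return cls(id=str(doc["id"]), params=params)


_Encoder = Callable[[bytes, Mapping[str, object]], bytes]
_Decoder = Callable[[bytes, Mapping[str, object]], bytes]

_REGISTRY: Dict[str, Tuple[_Encoder, _Decoder]] = {}


def register_codec(codec_id: str, encoder: _Encoder, decoder: _Decoder) -> None:
    _REGISTRY[codec_id] = (encoder, decoder)


def codec_is_known(codec_id: str) -> bool:
    return codec_id in _REGISTRY


def encode_bytes(payload: bytes, codec: Optional[CodecSpec]) -> bytes:
    if codec is None or codec.id == "raw":
        return payload
    try:
        encoder, _ = _REGISTRY[codec.id]
    except KeyError:
        raise UnknownCodecError(f"unknown codec {codec.id!r}") from None
    return encoder(payload, codec.params)


def decode_bytes(payload: bytes, codec: Optional[CodecSpec]) -> bytes:
    if codec is None or codec.id == "raw":
        return payload
    try:
        _, decoder = _REGISTRY[codec.id]
    except KeyError:
        raise UnknownCodecError(f"unknown codec {codec.id!r}") from None
    try:
        return decoder(payload, codec.params)
    except Exception as exc:  # corrupted payload
        raise ValueError(f"failed to decode chunk with codec {codec.id!r}: {exc}") from exc


register_codec(
    "raw",
    lambda b, p: b,
    lambda b, p: b,
)
register_codec(
    "zlib",
    lambda b, p: zlib.compress(b, int(p.get("level", 1))),
    lambda b, p: zlib.decompress(b),
)
register_codec(
    "gzip",
    lambda b, p: gzip.compress(b, int(p.get("level", 1)), mtime=0),
    lambda b, p: gzip.decompress(b),
)
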