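"""Runtime performance tuning for the long-running simulation loops."""

from __future__ import annotations

import ctypes

_tuned = False


def tune_malloc() -> None:
    """Keep large allocations on glibc's free lists instead of mmap.

    The training and inference loops allocate and release many multi-MB
    state buffers per iteration; with the default mmap threshold each epoch
    pays page-fault costs for freshly mapped memory. Raising the threshold
    lets the allocator recycle those blocks. No-op on non-glibc platforms.
    """
    global _tuned
    if _tuned:
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)   # M_MMAP_THRESHOLD
    except (OSError, AttributeError):
        pass
    _tuned = True
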