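"""Allocator tuning for array-heavy simulation loops.

The replicate pipeline allocates many short-lived matrices (covariances,
null-distribution workspaces) large enough that glibc serves each one with a
fresh mmap, so every allocation re-faults its pages.  Raising the mmap
threshold keeps these blocks on the heap, where they are recycled.  A no-op
on non-glibc platforms.
"""

from __future__ import annotations

import ctypes
import sys

_M_MMAP_THRESHOLD = -3


def keep_large_allocations_on_heap(threshold_bytes=512 * 1024 * 1024):
    if not sys.platform.startswith("linux"):
        return False
    try:
        libc = ctypes.CDLL("libc.so.6")
        return bool(libc.mallopt(_M_MMAP_THRESHOLD, threshold_bytes))
    except (OSError, AttributeError):
        return False
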