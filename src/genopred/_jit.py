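"""Optional numba acceleration.

Numerical kernels (MCMC sweep, coordinate descent) are written as plain
nopython-compatible functions. When numba is importable they are jitted;
otherwise the same code runs in pure Python, slower but identical in
behavior for a given seed path.
"""

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap
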