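"""Shared pytest configuration.

The presence of this file anchors the tests directory on sys.path so the
suite's `helpers` module (independent brute-force oracles) is importable
regardless of invocation style.
"""
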