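# Formula grammar

Expression trees serialize to two equivalent text forms.

## Infix text

```
expr    := term (("+" | "-") term)*
term    := factor (("*" | "/") factor)*
factor  := "-" factor | primary
primary := NUMBER
         | IDENT                      # feature reference
         | FUNC "(" expr ")"          # FUNC in {log, exp, sqrt, neg}
         | "(" expr ")"
NUMBER  := decimal or scientific literal (2, 2.5, .5, 1e-3)
IDENT   := [A-Za-z_][A-Za-z0-9_]*
```

Binary `+ -` bind loosest, `* /` tighter, unary minus and function
application tightest; `+ - * /` are left-associative, so
`x1 - x2 - x3` is `(x1 - x2) - x3` and `x1 + x2 * x3` is `x1 + (x2 * x3)`.
Identifiers outside the function set are feature references; when a feature
catalogue is supplied to `parse_formula`, unknown identifiers are rejected
with the character offset of the error. Constants are emitted with full
`repr` precision so a round trip through text preserves evaluation to
machine precision.

Operator semantics are the protected forms documented in
`mosr.expressions`: `a / 0 = 1`, `log(x <= 0) = 0`, `sqrt(x) = sqrt(|x|)`,
and `exp` clamps its argument to `[-50, 50]`.

## Nested JSON

Each node is one of:

```json
{"const": 2.5}
{"feature": "vo2_kg_at"}
{"op": "add", "children": [<node>, <node>]}
```

with `op` in `{add, sub, mul, div, neg, log, exp, sqrt}` and arity checked
on load (`from_json`).
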