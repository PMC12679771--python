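"""Exception hierarchy for the compiler.

Every failure that can be traced to a source location carries a 1-based
``line`` (and, for lexical errors, a 1-based ``column``).  Each exception
class exposes a stable machine-readable ``code`` used when the application
converts raised errors into validation issues, so that downstream tooling
can match on codes rather than message text.
"""

from __future__ import annotations


class CompileError(Exception):
    """Base class for all compiler-raised errors."""

    code: str = "compile-error"

    def __init__(self, message: str, *, line: int | None = None,
                 column: int | None = None, path: str | None = None):
        super().__init__(message)
        self.message = message
        self.line = line
        self.column = column
        self.path = path

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = ""
        if self.path:
            loc += f"{self.path}:"
        if self.line is not None:
            loc += f"{self.line}:"
            if self.column is not None:
                loc += f"{self.column}:"
        return f"{loc} {self.message}" if loc else self.message


# ---------------------------------------------------------------- fsh_core

class FshSyntaxError(CompileError):
    code = "syntax-error"


class EncodingError(CompileError):
    code = "decode-error"


class UnknownRuleSet(CompileError):
    code = "unknown-ruleset"


class ArityMismatch(CompileError):
    code = "arity-mismatch"


class CycleError(CompileError):
    """A RuleSet inserts itself, directly or transitively."""
    code = "ruleset-cycle"


class UnknownPath(CompileError):
    code = "unknown-path"


class ModeError(CompileError):
    """A FHIR-version-specific element used under the wrong mode."""
    code = "mode-error"


class TypeMismatch(CompileError):
    code = "type-mismatch"


# --------------------------------------------------------------- directives

class UnterminatedDirective(CompileError):
    code = "unterminated-directive"


class EmptyDirective(CompileError):
    code = "empty-directive"


class UnbalancedQuote(CompileError):
    code = "unbalanced-quote"


class MissingDirective(CompileError):
    code = "missing-directive"


class MultipleDirectives(CompileError):
    code = "multiple-directives"


# --------------------------------------------------------- plugin framework

class RegistryError(CompileError):
    code = "registry-error"


class UnknownPlugin(CompileError):
    code = "unknown-plugin"


class MissingRequired(CompileError):
    code = "missing-required-argument"


class UnknownFlag(CompileError):
    code = "unknown-flag"


class ArgumentValueError(CompileError):
    code = "invalid-argument"


class MutexViolation(CompileError):
    code = "mutex-violation"


class PluginError(CompileError):
    """Wraps an unexpected failure raised inside a plugin."""
    code = "plugin-error"


# ----------------------------------------------------------- tabular plugin

class FileMissing(CompileError):
    code = "file-missing"


class DecodeError(CompileError):
    code = "decode-error"


class RaggedRow(CompileError):
    code = "ragged-row"


class DuplicateCodeConflict(CompileError):
    code = "duplicate-display-conflict"


class EmptyCode(CompileError):
    code = "empty-code"


class UndeclaredProperty(CompileError):
    code = "undeclared-property"


class DanglingParent(CompileError):
    code = "dangling-parent"


# ----------------------------------------------------------------------- app

class NoSources(CompileError):
    code = "no-sources"


class PathMissing(CompileError):
    code = "path-missing"


# ---------------------------------------------------------------- fhir_model

class UndeclaredPropertyUse(CompileError):
    code = "undeclared-property"


class ModeVocabularyError(CompileError):
    """ConceptMap correspondence code from the wrong FHIR version's vocabulary."""
    code = "mode-vocabulary"


class OutputCollision(CompileError):
    code = "output-collision"
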