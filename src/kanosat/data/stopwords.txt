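# Small default stopword list shipped with kanosat.
# One token per line; lines starting with '#' are comments.
# Replace with a domain-specific list via the stopwords_path config key.
a
an
and
are
as
at
be
but
by
for
if
in
is
it
its
of
on
or
so
that
the
this
to
too
very
was
were
with
的
了
和
是
我
你
他
她
它
们
在
有
就
不
也
都
很
还
吧
吗
啊
呢
这
那
个
之
与
及
或
而
被
把
着
过
对
从
给

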