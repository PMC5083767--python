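patient_id,sex,birth_date,db_entry_date
P00000,F,1994-06-23,2007-01-11
P00001,F,1994-01-22,2002-05-03
P00002,F,1989-07-21,1996-01-18
P00003,F,1998-07-23,2002-09-21
P00004,F,1999-02-21,2011-04-15
P00005,F,1993-08-13,2007-04-04
P00006,M,1994-10-13,2007-01-10
P00007,M,1993-12-21,2005-02-19
P00008,F,1987-09-12,1994-01-01
P00009,F,1980-01-22,1994-05-19
P00010,F,1981-05-03,1995-05-07
P00011,F,1984-01-12,1994-01-04
P00012,M,1984-09-21,1994-01-01
P00013,M,1996-08-20,2003-10-23
P00014,F,1983-12-24,1994-01-01
P00015,M,1981-09-20,1994-02-22
P00016,M,1992-11-14,2005-10-11
P00017,M,1997-03-02,2009-08-28
P00018,F,2000-07-21,2001-03-01
P00019,M,1987-12-15,1997-12-20
P00020,M,1995-03-24,2005-11-24
P00021,F,1986-02-18,2002-01-08
P00022,F,1988-09-19,1995-02-25
P00023,F,1998-10-20,2008-10-27
P00024,M,1995-01-24,2002-02-26
P00025,F,1985-10-07,1994-01-01
P00026,M,1985-11-14,2002-03-24
P00027,M,1999-07-26,2008-09-30
P00028,F,1989-10-18,1994-02-15
P00029,F,1996-10-03,2010-07-09
P00030,F,1983-10-20,1995-06-17
P00031,M,1992-07-20,2007-10-22
P00032,F,1995-03-19,2008-07-31
P00033,M,1992-06-17,1995-12-10
P00034,F,1983-05-29,1994-01-01
P00035,F,1984-04-10,1995-07-25
P00036,M,1992-05-27,2004-06-17
P00037,M,1993-07-09,2001-08-13
P00038,F,1992-07-20,2007-05-25
P00039,F,1993-06-21,2000-07-05
P00040,M,2004-07-13,2004-05-13
P00041,F,1988-01-31,1994-01-01
P00042,F,1989-11-24,1996-07-31
P00043,F,1991-10-24,2002-09-14
P00044,F,1987-03-24,2000-04-06
P00045,F,1992-06-01,1994-02-11
P00046,M,1995-10-26,2006-05-02
P00047,M,1997-11-13,2010-08-07
P00048,M,1993-03-26,2005-09-10
P00049,F,1984-03-30,1995-05-29
P00050,M,1985-11-26,2002-07-25
P00051,M,1987-10-31,2002-11-13
P00052,M,1996-03-17,2003-04-07
P00053,F,1989-07-22,1998-10-13
P00054,M,1987-08-05,1998-06-18
P00055,M,1992-11-23,1994-07-29
P00056,F,2001-05-24,2006-01-17
P00057,F,2005-09-09,2009-02-01
P00058,F,1996-02-28,2005-05-29
P00059,M,1981-12-09,1994-01-01
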